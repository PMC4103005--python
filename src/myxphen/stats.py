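"""Per-strain randomization tests against wild type with FDR control.

Each mutant strain is compared to the pooled wild-type replicate set, one
trait at a time, with a two-group permutation (randomization) test on the
absolute difference of means. The test is distribution-free: the null is
generated by reassigning the pooled replicate values to two groups of the
original sizes. When the number of distinct reassignments C(n1+n2, n1) does
not exceed the iteration budget the null is enumerated exactly; otherwise
1000 Monte-Carlo reassignments are drawn and the add-one rule
p = (1 + #{null >= observed}) / (1 + iterations) keeps p strictly positive.

Multiplicity across the library is controlled with the
Benjamini-Hochberg-Yekutieli step-up procedure (valid under arbitrary
dependence), by default within each trait across strains.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import TraitTable

__all__ = [
    "randomization_test",
    "bhy_adjust",
    "call_mutants",
    "pleiotropy_summary",
]

_TIE_TOL = 1e-12


def randomization_test(
    mutant_values,
    wildtype_values,
    n_iterations: int = 1000,
    rng_seed: int | np.random.Generator | None = 0,
    method: str = "auto",
) -> tuple[float, float]:
    """Two-sided randomization test of mutant vs wild-type replicate means.

    Returns ``(observed_stat, p_raw)`` with ``observed_stat = |mean(mutant) -
    mean(wildtype)|``. With ``method="auto"`` exact enumeration replaces
    Monte-Carlo sampling when the number of distinct group reassignments is
    at most ``n_iterations``; ``"exact"`` and ``"monte-carlo"`` force either
    path. Null statistics within a relative 1e-12 of the observed one count
    as extreme (the identity reassignment always counts).
    """
    if method not in ("auto", "exact", "monte-carlo"):
        raise ValueError("method must be 'auto', 'exact' or 'monte-carlo'")
    x = np.asarray(mutant_values, dtype=float)
    y = np.asarray(wildtype_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need at least 2 replicate values")
    n1, n = x.size, x.size + y.size
    pooled = np.concatenate([x, y])
    total_sum = pooled.sum()
    observed = abs(x.mean() - y.mean())

    n_distinct = comb(n, n1)
    use_exact = (method == "exact"
                 or (method == "auto" and n_distinct <= n_iterations))
    tol = _TIE_TOL * max(1.0, observed)   # relative tie tolerance
    if use_exact:
        idx = np.fromiter(
            (i for c in combinations(range(n), n1) for i in c),
            dtype=np.intp, count=n_distinct * n1,
        ).reshape(n_distinct, n1)
        sum1 = pooled[idx].sum(axis=1)
        stats = np.abs(sum1 / n1 - (total_sum - sum1) / (n - n1))
        p = float((stats >= observed - tol).sum() / n_distinct)
    else:
        rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
               else np.random.default_rng(rng_seed))
        perms = rng.permuted(
            np.tile(pooled, (n_iterations, 1)), axis=1)
        sum1 = perms[:, :n1].sum(axis=1)
        stats = np.abs(sum1 / n1 - (total_sum - sum1) / (n - n1))
        hits = int((stats >= observed - tol).sum())
        p = (1.0 + hits) / (1.0 + n_iterations)
    return float(observed), float(p)


def bhy_adjust(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment under arbitrary dependence.

    For sorted p-values, p_adj(i) = min over j >= i of min(1, p(j) * m *
    c(m) / j) with c(m) the m-th harmonic number; output is restored to the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_by")[1]


def call_mutants(
    table: TraitTable,
    alpha: float = 0.05,
    n_iterations: int = 1000,
    rng_seed: int = 0,
    family: str = "trait",
    traits: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Randomization-test every (mutant strain, replicated trait) pair.

    Summary-only traits (count, timing) are excluded: they carry no replicate
    structure to resample. FDR adjustment is applied per ``family``:
    ``"trait"`` (default) adjusts within each trait across strains,
    ``"all"`` across all strain x trait tests jointly.

    Returns a frame with columns ``strain, trait, observed_stat, p_raw,
    p_adj, significant, n_iterations, exact``; deterministic for a fixed
    ``rng_seed``.
    """
    if family not in ("trait", "all"):
        raise ValueError("family must be 'trait' or 'all'")
    test_traits = tuple(
        t for t in (traits or table.traits) if t in table.replicate_traits
    )
    mutants = table.mutants
    if not mutants:
        raise ValueError("table contains no mutant strains")

    # per-test independent substreams, order-stable
    children = np.random.SeedSequence(rng_seed).spawn(
        len(test_traits) * len(mutants))

    wide = {
        t: {s: g["value"].to_numpy(float)
            for s, g in table.df[table.df["trait"] == t].groupby("strain")}
        for t in test_traits
    }

    rows = []
    i = 0
    for trait in test_traits:
        wt = wide[trait][table.wildtype]
        for strain in mutants:
            vals = wide[trait][strain]
            rng = np.random.default_rng(children[i])
            i += 1
            obs, p = randomization_test(vals, wt, n_iterations, rng)
            exact = comb(vals.size + wt.size, vals.size) <= n_iterations
            rows.append((strain, trait, obs, p, exact))
    res = pd.DataFrame(
        rows, columns=["strain", "trait", "observed_stat", "p_raw", "exact"])
    res["n_iterations"] = n_iterations

    if family == "all":
        res["p_adj"] = bhy_adjust(res["p_raw"].to_numpy())
    else:
        res["p_adj"] = np.nan
        for trait in test_traits:
            m = res["trait"] == trait
            res.loc[m, "p_adj"] = bhy_adjust(res.loc[m, "p_raw"].to_numpy())
    res["significant"] = res["p_adj"] <= alpha
    return res[["strain", "trait", "observed_stat", "p_raw", "p_adj",
                "significant", "n_iterations", "exact"]]


def pleiotropy_summary(results: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Count significant traits per strain and summarize pleiotropy.

    Returns ``(per_strain, fractions)`` where ``per_strain`` has one row per
    strain with its number of significant traits, and ``fractions`` reports
    the fraction of strains with >= 1 significant trait (strains
    distinguishable from wild type at all) and with >= 2 (pleiotropic).
    """
    per_strain = (
        results.groupby("strain", sort=False)["significant"]
        .sum().astype(int).rename("n_significant_traits").reset_index()
    )
    n = len(per_strain)
    ge1 = int((per_strain["n_significant_traits"] >= 1).sum())
    ge2 = int((per_strain["n_significant_traits"] >= 2).sum())
    fractions = {
        "n_strains": n,
        "n_ge1": ge1,
        "n_ge2": ge2,
        "frac_ge1": ge1 / n if n else float("nan"),
        "frac_ge2": ge2 / n if n else float("nan"),
    }
    return per_strain, fractions
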