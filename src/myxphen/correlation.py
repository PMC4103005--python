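"""Trait-trait association analysis: zero-order and partial Spearman.

Pleiotropy leaves a correlation signature: if one gene disruption moves two
traits together, the traits correlate across the library. Eleven variables
enter the analysis — the 8 trait summaries plus the within-swarm variability
of area, grayness and circularity expressed as coefficients of variation
(SD normalized by the mean, so large variability is not a mere consequence
of large averages).

Zero-order associations are Spearman rank correlations (pairwise-complete).
Partial associations condition each pair on *all* nine remaining variables:
variables are rank-transformed, the rank-correlation matrix R is inverted,
and rho_ij.rest = -Q_ij / sqrt(Q_ii * Q_jj) with Q = R^-1 (listwise-complete,
since the precision matrix needs a common sample). p-values use the
t-approximation with df = n - 2 (zero-order) or n - 2 - #controls (partial).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import TRAITS, VARIABILITY_TRAITS, TraitTable

__all__ = [
    "cv_normalize",
    "build_strain_trait_matrix",
    "spearman_matrix",
    "partial_spearman_matrix",
    "significance_marks",
    "correlation_report",
]


def cv_normalize(means, sds) -> np.ndarray:
    """Elementwise coefficient of variation sd/|mean|.

    Entries with zero mean are flagged missing (NaN) with a warning; a zero
    SD yields 0. The absolute mean keeps CVs non-negative should a summary
    value stray below zero.
    """
    m = np.asarray(means, dtype=float)
    s = np.asarray(sds, dtype=float)
    if m.shape != s.shape:
        raise ValueError("means and sds must have the same length")
    out = np.full(m.shape, np.nan)
    nz = m != 0
    out[nz] = s[nz] / np.abs(m[nz])
    n_zero = int((~nz & ~np.isnan(m)).sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} zero-mean entries flagged missing in CV normalization",
            stacklevel=2)
    return out


def build_strain_trait_matrix(
    table: TraitTable, include_wildtype: bool = False
) -> pd.DataFrame:
    """Per-strain matrix of the 11 analysis variables.

    Columns: the 8 trait summaries plus ``area_std``, ``grayness_std`` and
    ``circularity_std`` (CV-normalized replicate SDs). The wild type is
    excluded by default — the correlation analysis concerns variation among
    mutants.
    """
    summ = table.summary_matrix(include_wildtype=include_wildtype)
    sds = table.sd_matrix(VARIABILITY_TRAITS)
    if not include_wildtype:
        sds = sds.drop(index=table.wildtype, errors="ignore")
    out = summ.copy()
    for t in VARIABILITY_TRAITS:
        out[f"{t}_std"] = cv_normalize(
            summ[t].to_numpy(), sds.loc[summ.index, t].to_numpy())
    order = [t for t in TRAITS if t in out.columns] + [
        f"{t}_std" for t in VARIABILITY_TRAITS]
    return out[order]


def _check_matrix(matrix: pd.DataFrame, min_n: int = 3) -> None:
    n_ok = matrix.notna().sum(axis=0)
    bad = n_ok[n_ok < min_n]
    if len(bad):
        raise ValueError(
            f"variables with fewer than {min_n} non-missing strains: "
            f"{list(bad.index)}")


def spearman_matrix(
    matrix: pd.DataFrame, min_n: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise zero-order Spearman rho, two-sided p, and n per pair.

    Average-rank tie handling; pairwise-complete observations; constant
    variables yield NaN. Matrices are symmetric with unit diagonal.
    """
    _check_matrix(matrix, min_n)
    cols = list(matrix.columns)
    k = len(cols)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    nmat = np.zeros((k, k), int)
    X = matrix.to_numpy(float)
    nmat[np.diag_indices(k)] = np.sum(~np.isnan(X), axis=0)
    for i in range(k):
        for j in range(i + 1, k):
            ok = ~np.isnan(X[:, i]) & ~np.isnan(X[:, j])
            n = int(ok.sum())
            nmat[i, j] = nmat[j, i] = n
            if n < min_n or np.unique(X[ok, i]).size < 2 \
                    or np.unique(X[ok, j]).size < 2:
                rho[i, j] = rho[j, i] = np.nan
                pval[i, j] = pval[j, i] = np.nan
                continue
            r, p = sps.spearmanr(X[ok, i], X[ok, j])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    as_df = lambda a: pd.DataFrame(a, index=cols, columns=cols)
    return as_df(rho), as_df(pval), as_df(nmat)


def partial_spearman_matrix(
    matrix: pd.DataFrame, ridge: float = 0.0
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Full-conditioning partial Spearman via the rank precision matrix.

    Each pair is conditioned on all remaining variables simultaneously.
    Listwise-complete rows only. If the rank-correlation matrix is singular,
    a small diagonal ridge is retried once; persistent singularity raises a
    ``ValueError`` naming the collinear variables.
    """
    _check_matrix(matrix)
    cols = list(matrix.columns)
    k = len(cols)
    complete = matrix.dropna()
    n = len(complete)
    if n < k + 3:
        raise ValueError(
            f"only {n} complete strains for {k} variables; partial "
            "correlation needs more observations than variables")
    ranks = complete.rank(method="average").to_numpy(float)
    R = np.corrcoef(ranks, rowvar=False)
    return _partial_with_p(R, cols, n, k, ridge)


def _invert(Rm):
    try:
        Q = np.linalg.inv(Rm)
    except np.linalg.LinAlgError:
        return None
    return Q if np.isfinite(Q).all() else None


def partial_from_correlation(R: np.ndarray) -> np.ndarray:
    """Full-conditioning partial correlations from a correlation matrix.

    rho_ij.rest = -Q_ij / sqrt(Q_ii * Q_jj) with Q = R^-1; for three
    variables this reduces to the first-order recursive formula
    (r12 - r13*r23) / sqrt((1-r13^2)(1-r23^2)).
    """
    R = np.asarray(R, dtype=float)
    Q = np.linalg.inv(R)
    d = np.sqrt(np.diag(Q))
    partial = -Q / np.outer(d, d)
    np.fill_diagonal(partial, 1.0)
    return partial


def _partial_with_p(R, cols, n, k, ridge):
    offdiag = np.abs(R - np.eye(k))
    if offdiag.max() >= 1.0 - 1e-12:
        i, j = np.unravel_index(np.argmax(offdiag), R.shape)
        raise ValueError(
            "perfectly collinear variables make the partial correlation "
            f"undefined: {cols[i]!r} / {cols[j]!r}")
    Q = _invert(R)
    if Q is None or np.linalg.cond(R) > 1e12:
        Q = _invert(R + (ridge or 1e-8) * np.eye(k))
        if Q is None:
            corr_offdiag = np.abs(R - np.eye(k))
            i, j = np.unravel_index(np.argmax(corr_offdiag), R.shape)
            raise ValueError(
                "rank-correlation matrix singular even after regularization; "
                f"most collinear pair: {cols[i]!r} / {cols[j]!r}")
        warnings.warn("singular rank-correlation matrix; ridge applied",
                      stacklevel=2)

    d = np.sqrt(np.diag(Q))
    partial = -Q / np.outer(d, d)
    np.fill_diagonal(partial, 1.0)
    partial = np.clip(partial, -1.0, 1.0)

    g = k - 2                      # number of controlled variables per pair
    df = n - 2 - g
    if df < 1:
        raise ValueError("not enough complete observations for p-values")
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = partial * np.sqrt(df / (1.0 - partial**2))
    pval = 2.0 * sps.t.sf(np.abs(tstat), df)
    pval = np.where(np.abs(partial) >= 1.0, 0.0, pval)
    np.fill_diagonal(pval, 0.0)
    as_df = lambda a: pd.DataFrame(a, index=cols, columns=cols)
    return as_df(partial), as_df(pval), n


def significance_marks(pvals: pd.DataFrame) -> pd.DataFrame:
    """Two-level annotation: '**' for p <= 0.01, '*' for p <= 0.05."""
    marks = pd.DataFrame("", index=pvals.index, columns=pvals.columns)
    marks = marks.where(~(pvals <= 0.05), "*")
    marks = marks.where(~(pvals <= 0.01), "**")
    return marks


def correlation_report(table: TraitTable, include_wildtype: bool = False) -> dict:
    """Convenience wrapper: build the 11-variable matrix and both analyses."""
    m = build_strain_trait_matrix(table, include_wildtype=include_wildtype)
    rho, p, nmat = spearman_matrix(m)
    prho, pp, n_used = partial_spearman_matrix(m)
    return {
        "matrix": m,
        "zero_order_rho": rho,
        "zero_order_p": p,
        "zero_order_n": nmat,
        "zero_order_marks": significance_marks(p),
        "partial_rho": prho,
        "partial_p": pp,
        "partial_marks": significance_marks(pp),
        "n_listwise": n_used,
    }
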