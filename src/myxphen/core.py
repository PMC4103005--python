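"""Core containers and trait vocabulary for the phenotype-profiling pipeline.

The central object is the :class:`TraitTable`: a tidy, replicate-level table of
phenotype measurements for a mutant-strain library plus one designated
wild-type strain. Eight traits are tracked:

* six replicated, testable traits — fruiting-body ``area`` (px), ``circularity``
  (isoperimetric ratio), ``grayness`` (mean 8-bit intensity of aggregates),
  swarm expansion on soft (0.4%) and hard (1.5%) agar (``soft``/``hard``, mm),
  and ``sporulation`` efficiency (% of wild type);
* two summary-only traits — aggregate ``count`` (one non-negative integer per
  strain) and developmental ``timing`` (one ordinal level per strain, five
  discrete observation intervals), which carry no replicate structure and are
  therefore excluded from the per-strain randomization test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical trait order used throughout the package
TRAITS: tuple[str, ...] = (
    "area",
    "circularity",
    "grayness",
    "count",
    "timing",
    "soft",
    "hard",
    "sporulation",
)

#: traits with replicate-level measurements; these enter the randomization test
REPLICATE_TRAITS: tuple[str, ...] = (
    "area",
    "circularity",
    "grayness",
    "soft",
    "hard",
    "sporulation",
)

#: traits recorded as a single summary value per strain
SUMMARY_TRAITS: tuple[str, ...] = ("count", "timing")

#: the six development-associated traits (no swarm expansion)
DEVELOPMENT_TRAITS: tuple[str, ...] = (
    "area",
    "circularity",
    "grayness",
    "count",
    "timing",
    "sporulation",
)

#: traits whose within-swarm variability is analysed as an extra CV variable
VARIABILITY_TRAITS: tuple[str, ...] = ("area", "grayness", "circularity")

#: default wild-type strain identifier
WILDTYPE: str = "DK1622"

#: ordinal timing level -> hours post-starvation
TIMING_HOURS: dict[int, int] = {1: 24, 2: 48, 3: 72, 4: 96, 5: 120}

_COLUMNS = ("strain", "trait", "replicate", "value")


class TraitTableError(ValueError):
    """Raised when a trait table violates its schema or invariants."""


@dataclass
class TraitTable:
    """Replicate-level phenotype measurements in long (tidy) format.

    Parameters
    ----------
    df
        Long-format frame with columns ``strain``, ``trait``, ``replicate``,
        ``value``.
    wildtype
        Identifier of the designated wild-type strain; must be present.
    replicate_traits
        Traits that must have >= 2 replicate values per strain (testable).
    """

    df: pd.DataFrame
    wildtype: str = WILDTYPE
    replicate_traits: tuple[str, ...] = field(default=REPLICATE_TRAITS)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise TraitTableError(f"trait table missing columns: {missing}")
        if len(self.df) == 0:
            raise TraitTableError("trait table is empty")
        dup = self.df.duplicated(subset=["strain", "trait", "replicate"])
        if dup.any():
            rows = self.df.loc[dup, ["strain", "trait", "replicate"]].head(5)
            raise TraitTableError(
                f"duplicate (strain, trait, replicate) keys, e.g.\n{rows}"
            )
        if self.wildtype not in set(self.df["strain"]):
            raise TraitTableError(
                f"designated wild-type strain {self.wildtype!r} not in table"
            )
        counts = (
            self.df[self.df["trait"].isin(self.replicate_traits)]
            .groupby(["strain", "trait"], sort=False)["value"]
            .size()
        )
        bad = counts[counts < 2]
        if len(bad):
            raise TraitTableError(
                f"testable (strain, trait) pairs with <2 replicates: "
                f"{list(bad.index[:5])}"
            )

    # -- accessors ---------------------------------------------------------

    @property
    def strains(self) -> list[str]:
        """Strain ids in first-appearance order."""
        return list(dict.fromkeys(self.df["strain"]))

    @property
    def mutants(self) -> list[str]:
        return [s for s in self.strains if s != self.wildtype]

    @property
    def traits(self) -> list[str]:
        return list(dict.fromkeys(self.df["trait"]))

    def values(self, strain: str, trait: str) -> np.ndarray:
        """Replicate values for one (strain, trait) pair."""
        m = (self.df["strain"] == strain) & (self.df["trait"] == trait)
        return self.df.loc[m, "value"].to_numpy(dtype=float)

    def summary_matrix(self, include_wildtype: bool = True) -> pd.DataFrame:
        """Per-strain summary values (replicate mean; single values as-is)."""
        piv = self.df.pivot_table(
            index="strain", columns="trait", values="value", aggfunc="mean"
        )
        order = [t for t in TRAITS if t in piv.columns] + [
            t for t in piv.columns if t not in TRAITS
        ]
        piv = piv.loc[self.strains, order]
        if not include_wildtype:
            piv = piv.drop(index=self.wildtype)
        piv.columns.name = None
        return piv

    def sd_matrix(self, traits: tuple[str, ...] = VARIABILITY_TRAITS) -> pd.DataFrame:
        """Per-strain sample SD across replicates for the given traits."""
        sub = self.df[self.df["trait"].isin(traits)]
        piv = sub.pivot_table(
            index="strain", columns="trait", values="value", aggfunc=lambda v: v.std(ddof=1)
        )
        piv = piv.loc[self.strains, [t for t in traits if t in piv.columns]]
        piv.columns.name = None
        return piv

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, wildtype: str = WILDTYPE,
                 replicate_traits: tuple[str, ...] = REPLICATE_TRAITS) -> "TraitTable":
        try:
            df = pd.read_csv(path, sep="\t")
        except pd.errors.EmptyDataError as exc:
            raise TraitTableError(f"empty trait table file: {path}") from exc
        return cls(df, wildtype=wildtype, replicate_traits=replicate_traits)
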