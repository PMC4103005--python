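"""Expression time-course clustering and phenotype co-clustering.

Developmental expression profiles (genes x hours post-starvation, log scale)
are normalized with a simple, self-contained two-step scheme — per-gene
median centering followed by per-array (column) z-scaling — then clustered
hierarchically with average linkage on correlation distance (1 - Pearson),
the convention of classic expression-clustering tools, and cut into k = 4
temporal classes. Cluster membership is cross-tabulated against the
phenotype-derived strain groups (each gene maps to its disruption strain),
and per-cell over-representation is scored with one-sided hypergeometric
tests, Benjamini-Yekutieli-adjusted across cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .multivariate import ClusterResult, hierarchical_cluster
from .stats import bhy_adjust

__all__ = [
    "normalize_expression",
    "average_linkage_cluster",
    "CoClusterTable",
    "cocluster_enrichment",
]


def normalize_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene median centering, then per-array (column) z-scaling.

    Location-invariant per gene: adding a constant to one gene's profile
    leaves its normalized profile (and everyone else's) unchanged. Genes with
    constant profiles are flagged with a warning — they carry no temporal
    signal.
    """
    m = pd.DataFrame(matrix).astype(float)
    if m.shape[1] < 3:
        raise ValueError("need at least 3 timepoint columns")
    constant = m.index[m.nunique(axis=1) <= 1]
    if len(constant):
        warnings.warn(
            f"{len(constant)} constant gene profiles flagged: "
            f"{list(constant[:5])}", stacklevel=2)
    centered = m.sub(m.median(axis=1), axis=0)
    sds = centered.std(axis=0, ddof=1)
    sds = sds.replace(0.0, 1.0)           # degenerate arrays left centered
    return centered.sub(centered.mean(axis=0), axis=1).div(sds, axis=1)


def average_linkage_cluster(
    matrix: pd.DataFrame, k: int = 4, metric: str = "correlation"
) -> ClusterResult:
    """Average-linkage hierarchical clustering of gene profiles, cut at k.

    Correlation distance by default (Euclidean available via ``metric``).
    Constant-profile genes are excluded with a warning under correlation
    distance, where their distance is undefined.
    """
    m = pd.DataFrame(matrix).astype(float)
    if metric == "correlation":
        constant = m.index[m.std(axis=1, ddof=0) == 0]
        if len(constant):
            warnings.warn(
                f"excluding {len(constant)} constant-profile genes from "
                "correlation-distance clustering", stacklevel=2)
            m = m.drop(index=constant)
    if k > len(m):
        raise ValueError(f"k={k} exceeds {len(m)} usable genes")
    return hierarchical_cluster(m, k=k, axis="strains",
                                method="average", metric=metric)


@dataclass
class CoClusterTable:
    """Expression-cluster x phenotype-group contingency with enrichment."""

    counts: pd.DataFrame        # expression clusters (rows) x phenotype groups
    p_values: pd.DataFrame      # one-sided hypergeometric, per cell
    p_adjusted: pd.DataFrame    # BHY across cells
    fractions: pd.DataFrame     # row-wise composition (pie-chart content)
    n_items: int = 0


def cocluster_enrichment(
    expr_labels: pd.Series,
    pheno_labels: pd.Series,
    mapping: dict | pd.Series | None = None,
) -> CoClusterTable:
    """Cross-tabulate expression clusters against phenotype groups.

    ``mapping`` sends gene ids to strain ids (identity by default: the
    library carries one disruption strain per gene). Only items classified in
    both label sets enter. Each cell's p-value is the one-sided
    hypergeometric probability of at least the observed overlap given the
    marginals; adjustment is Benjamini-Yekutieli across all cells.
    """
    expr_labels = pd.Series(expr_labels)
    pheno_labels = pd.Series(pheno_labels)
    if mapping is not None:
        mapping = pd.Series(mapping)
        expr_labels = expr_labels.rename(index=mapping.to_dict())
    common = expr_labels.index.intersection(pheno_labels.index)
    if len(common) == 0:
        raise ValueError("no items shared between expression and phenotype "
                         "classifications (check the gene-strain mapping)")
    e = expr_labels.loc[common]
    g = pheno_labels.loc[common]
    counts = pd.crosstab(e, g)
    counts.index.name = "expression_cluster"
    counts.columns.name = "phenotype_group"

    N = int(counts.to_numpy().sum())
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    pv = counts.astype(float).copy()
    for i in counts.index:
        for j in counts.columns:
            k_obs = int(counts.loc[i, j])
            pv.loc[i, j] = sps.hypergeom.sf(
                k_obs - 1, N, int(row_tot[i]), int(col_tot[j]))
    padj = pd.DataFrame(
        bhy_adjust(pv.to_numpy().ravel()).reshape(pv.shape),
        index=pv.index, columns=pv.columns)
    fractions = counts.div(row_tot, axis=0)
    return CoClusterTable(counts=counts, p_values=pv, p_adjusted=padj,
                          fractions=fractions, n_items=N)
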