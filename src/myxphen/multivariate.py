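"""z-score standardization, Ward clustering, and PCA of trait profiles.

Traits live on wildly different scales (pixels, millimetres, ordinal levels),
so profiles are first converted column-wise to z-scores (sample SD). Strains
and traits are then clustered with Ward linkage on Euclidean distances of the
z-scores — the strain dendrogram cut at k = 4 groups and the trait dendrogram
at k = 2, the group counts resolved by the library analysis. PCA is an
eigendecomposition of the covariance of the z-scores (equivalently,
correlation-matrix PCA), with a deterministic sign convention: each
component's largest-magnitude loading is made positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "ZScoreMatrix",
    "ClusterResult",
    "PCAResult",
    "zscore",
    "ward_cluster",
    "hierarchical_cluster",
    "pca",
    "trait_group_report",
    "linkage_to_newick",
    "cluster_heatmap",
]


@dataclass
class ZScoreMatrix:
    """Column-standardized matrix retaining the original location/scale."""

    values: pd.DataFrame
    means: pd.Series
    sds: pd.Series

    def invert(self) -> pd.DataFrame:
        """Undo the standardization (round-trip identity)."""
        return self.values * self.sds + self.means


@dataclass
class ClusterResult:
    """Hierarchical-clustering output for one axis (strains or traits)."""

    linkage: np.ndarray                 # scipy linkage matrix
    labels: pd.Series                   # item -> group id (1..k)
    order: list[str]                    # dendrogram leaf order
    axis: str = "strains"
    method: str = "ward"
    metric: str = "euclidean"

    @property
    def k(self) -> int:
        return int(self.labels.nunique())

    def group_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


@dataclass
class PCAResult:
    """Loadings (traits x components), scores (strains x components), and
    per-component variance explained in percent (sums to 100)."""

    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_explained: np.ndarray = field(default_factory=lambda: np.array([]))


def zscore(matrix: pd.DataFrame, ddof: int = 1) -> ZScoreMatrix:
    """Column-wise (x - mean) / SD with sample SD.

    Constant and all-missing columns are dropped with a warning — they carry
    no between-strain information and would divide by zero.
    """
    matrix = pd.DataFrame(matrix).astype(float)
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0, ddof=ddof)
    bad = [c for c in matrix.columns
           if not np.isfinite(sds[c]) or sds[c] == 0]
    if bad:
        warnings.warn(f"dropping constant/empty columns: {bad}", stacklevel=2)
        matrix = matrix.drop(columns=bad)
        means = means.drop(bad)
        sds = sds.drop(bad)
    if matrix.shape[1] == 0:
        raise ValueError("no non-constant columns left to standardize")
    z = (matrix - means) / sds
    return ZScoreMatrix(values=z, means=means, sds=sds)


def hierarchical_cluster(
    matrix: pd.DataFrame,
    k: int,
    axis: str = "strains",
    method: str = "ward",
    metric: str = "euclidean",
) -> ClusterResult:
    """Cluster rows (``axis='strains'``) or columns (``'traits'``) and cut at k."""
    if axis not in ("strains", "traits"):
        raise ValueError("axis must be 'strains' or 'traits'")
    data = matrix if axis == "strains" else matrix.T
    items = list(data.index)
    if k > len(items):
        raise ValueError(f"k={k} exceeds {len(items)} items on axis {axis!r}")
    dists = pdist(data.to_numpy(float), metric=metric)
    if not np.isfinite(dists).all():
        raise ValueError("non-finite distances; check for missing values or "
                         "constant profiles under correlation distance")
    Z = hierarchy.linkage(dists, method=method)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    order = [items[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(
        linkage=Z, labels=pd.Series(flat, index=items, name="group"),
        order=order, axis=axis, method=method, metric=metric)


def ward_cluster(z: ZScoreMatrix | pd.DataFrame, axis: str = "strains",
                 k: int = 4) -> ClusterResult:
    """Ward linkage on Euclidean distances of z-scores, cut at k groups."""
    matrix = z.values if isinstance(z, ZScoreMatrix) else z
    return hierarchical_cluster(matrix, k=k, axis=axis,
                                method="ward", metric="euclidean")


def pca(z: ZScoreMatrix | pd.DataFrame) -> PCAResult:
    """PCA of the trait covariance of z-scores.

    Components are sorted by decreasing variance; eigenvalues of
    rank-deficient inputs are clipped at zero and reported as 0%. The
    variance-explained vector sums to exactly 100 (up to float round-off).
    """
    matrix = z.values if isinstance(z, ZScoreMatrix) else pd.DataFrame(z)
    if matrix.shape[1] < 2 or matrix.shape[0] < 3:
        raise ValueError("PCA needs >= 2 traits and >= 3 strains")
    X = matrix.to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("PCA input contains missing values")
    Xc = X - X.mean(axis=0)
    cov = np.cov(Xc, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    idx = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[idx], 0.0, None)
    eigvec = eigvec[:, idx]
    # deterministic orientation: largest-|loading| entry positive
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    var_pct = 100.0 * eigval / eigval.sum()
    comps = [f"PC{i+1}" for i in range(eigvec.shape[1])]
    loadings = pd.DataFrame(eigvec, index=matrix.columns, columns=comps)
    scores = pd.DataFrame(Xc @ eigvec, index=matrix.index, columns=comps)
    return PCAResult(loadings=loadings, scores=scores,
                     variance_explained=var_pct)


def trait_group_report(cluster: ClusterResult,
                       matrix: pd.DataFrame | None = None,
                       stability_threshold: float = 0.2) -> dict:
    """Named trait groups with an optional stability flag.

    When the underlying matrix is provided, a mean silhouette width below
    ``stability_threshold`` marks the grouping as unstable (uncorrelated
    traits produce essentially arbitrary splits).
    """
    groups = {
        f"group_{g}": sorted(cluster.labels.index[cluster.labels == g])
        for g in sorted(cluster.labels.unique())
    }
    report: dict = {"groups": groups, "k": cluster.k}
    if matrix is not None and 1 < cluster.k < len(cluster.labels):
        from sklearn.metrics import silhouette_score

        data = matrix if cluster.axis == "strains" else matrix.T
        sil = float(silhouette_score(
            data.loc[cluster.labels.index].to_numpy(float),
            cluster.labels.to_numpy(), metric=cluster.metric))
        report["silhouette"] = sil
        report["stable"] = sil >= stability_threshold
    return report


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage tree to Newick with merge-height branch lengths."""
    tree = hierarchy.to_tree(Z)

    def build(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return build(tree, tree.dist) + ";"


def cluster_heatmap(z: ZScoreMatrix | pd.DataFrame,
                    strain_cluster: ClusterResult,
                    trait_cluster: ClusterResult,
                    path=None):
    """Heatmap of z-scores ordered by both dendrograms (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matrix = z.values if isinstance(z, ZScoreMatrix) else z
    ordered = matrix.loc[strain_cluster.order, trait_cluster.order]
    fig, ax = plt.subplots(figsize=(6, 10))
    vmax = np.nanpercentile(np.abs(ordered.to_numpy()), 98)
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(ordered.columns)))
    ax.set_xticklabels(ordered.columns, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.set_ylabel(f"{len(ordered)} strains (dendrogram order)")
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
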