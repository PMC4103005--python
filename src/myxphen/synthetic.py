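"""Synthetic phenotype, image, and expression data with known ground truth.

This module emulates the structure of a 181-strain (180 mutants + wild type),
8-trait phenotype screen so that every downstream stage — image trait
extraction, randomization testing, correlation, clustering, PCA, and
expression co-clustering — can be exercised and validated against planted
truth without access to the original measurements.

The generative model
--------------------
Replicate values for strain *s* and trait *t* are drawn as::

    value = baseline_mean_t + shift_{s,t} + Normal(0, sd_t),   sd_t = cv_t * baseline_mean_t

Planted effects come from a latent multivariate-Gaussian copula over the 8
traits: each mutant draws ``z_s ~ MVN(0, trait_correlation)`` and trait *t* is
*affected* when ``|z_{s,t}|`` exceeds the two-sided tail cut ``c_q``, with the
per-trait tail probability ``q = 1 - (1 - effect_fraction)^(1/8)`` chosen so
that (under independence) a fraction ``effect_fraction`` of mutants carries at
least one effect. Affected pairs are shifted by ``effect_size_sd * sd_t *
z_{s,t}`` — correlated shifts are exactly what planted pleiotropy means here.
Optionally, strains are partitioned into ``n_groups`` phenotype-severity
groups whose centroid patterns are shifted by ``group_separation_sd`` replicate
SDs; this is off (0.0) by default so that ``effect_fraction = 0`` yields a
pure null table.

``count`` is emitted as a single Poisson integer per strain and ``timing`` as
a single ordinal level in 1..5 (five discrete observation intervals); neither
carries replicate structure. ``sporulation`` is floored at 0.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    REPLICATE_TRAITS,
    SUMMARY_TRAITS,
    TRAITS,
    WILDTYPE,
    TraitTable,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "Blob",
    "ImageSpec",
    "default_trait_correlation",
    "default_group_patterns",
    "simulate_trait_table",
    "simulate_development_image",
    "random_image_spec",
    "default_cluster_profiles",
    "simulate_expression_matrix",
]


# ---------------------------------------------------------------------------
# trait-table simulation
# ---------------------------------------------------------------------------

#: wild-type baseline means, in trait units (area px; grayness 8-bit intensity;
#: soft/hard swarm diameter mm; sporulation % of wild type; timing ordinal level)
DEFAULT_BASELINE_MEANS: dict[str, float] = {
    "area": 5000.0,
    "circularity": 0.72,
    "grayness": 140.0,
    "count": 30.0,
    "timing": 3.0,
    "soft": 11.0,
    "hard": 9.0,
    "sporulation": 100.0,
}

#: replicate-level coefficients of variation (sd = cv * mean)
DEFAULT_BASELINE_CVS: dict[str, float] = {
    "area": 0.30,
    "circularity": 0.08,
    "grayness": 0.08,
    "count": 0.25,
    "timing": 0.27,
    "soft": 0.12,
    "hard": 0.10,
    "sporulation": 0.35,
}


def default_trait_correlation() -> np.ndarray:
    """Latent trait-trait correlation (pleiotropy structure), 8x8 PSD.

    Built from a three-factor loading model so positive semi-definiteness
    holds by construction: factor A ties the swarm/shape block (soft, hard,
    area, circularity), factor B the development/opacity block (timing,
    grayness, negatively coupled to A), and factor C count + sporulation.
    The sign pattern mirrors the observed trait associations: small-area,
    low-circularity, slow-swarming strains tend to be lighter (higher
    grayness) and delayed (higher timing).
    """
    loadings = {
        "area":         (0.60, -0.15, 0.10),
        "circularity":  (0.60, -0.15, 0.00),
        "grayness":     (-0.30, 0.65, 0.00),
        "count":        (-0.20, 0.15, 0.60),
        "timing":       (-0.30, 0.65, 0.15),
        "soft":         (0.60, -0.10, 0.15),
        "hard":         (0.60, -0.10, -0.15),
        "sporulation":  (0.15, 0.00, 0.60),
    }
    L = np.array([loadings[t] for t in TRAITS])
    corr = L @ L.T
    np.fill_diagonal(corr, 1.0)
    return corr


def default_group_patterns() -> np.ndarray:
    """Centroid sign patterns (4 x 8) for the planted strain groups.

    Each row holds the group's characteristic traits as +-1 (scaled by
    ``group_separation_sd`` replicate SDs per trait, the same unit as
    ``effect_size_sd``). Group severity mimics the four phenotype classes
    seen in the library: row 0 — severe (small, irregular, light, delayed,
    poor swarming and sporulation, high count); row 1 — moderate (shape,
    swarming, timing); row 2 — wild-type-like (all zero; the wild type
    itself is assigned here); row 3 — mildly enhanced circularity/swarming
    with lower count.
    """
    idx = {t: i for i, t in enumerate(TRAITS)}
    pat = np.zeros((4, len(TRAITS)))
    severe = {"area": -1.0, "circularity": -1.0, "grayness": 1.0, "count": 1.0,
              "timing": 1.0, "soft": -1.0, "hard": -1.0, "sporulation": -1.0}
    moderate = {"circularity": -1.0, "soft": -1.0, "hard": -1.0, "timing": 1.0}
    mild = {"circularity": 1.0, "soft": 1.0, "hard": 1.0, "count": -1.0}
    for t, v in severe.items():
        pat[0, idx[t]] = v
    for t, v in moderate.items():
        pat[1, idx[t]] = v
    for t, v in mild.items():
        pat[3, idx[t]] = v
    return pat


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic trait table."""

    n_strains: int = 181                      # 180 mutants + 1 wild type
    n_replicates: int = 3
    n_replicates_wildtype: int = 24           # pooled wild-type reference set
    trait_names: tuple[str, ...] = TRAITS
    baseline_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_MEANS))
    baseline_cvs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_CVS))
    effect_fraction: float = 0.86
    #: optional override: affect each (strain, trait) with this marginal
    #: probability instead of deriving the cut from ``effect_fraction``
    per_trait_effect_prob: float | None = None
    effect_size_sd: float = 3.0
    trait_correlation: np.ndarray = field(
        default_factory=default_trait_correlation)
    n_groups: int = 4
    group_separation_sd: float = 0.0
    rng_seed: int = 0

    def validate(self) -> None:
        C = np.asarray(self.trait_correlation, dtype=float)
        k = len(self.trait_names)
        if C.shape != (k, k):
            raise ValueError(
                f"trait_correlation must be {k}x{k}, got {C.shape}")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("trait_correlation is not symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-10):
            raise ValueError("trait_correlation diagonal must be 1")
        eigmin = np.linalg.eigvalsh(C).min()
        if eigmin < -1e-10:
            raise ValueError(
                "trait_correlation is not positive semidefinite "
                f"(smallest eigenvalue {eigmin:.3e})")
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise ValueError("effect_fraction must lie in [0, 1]")
        if self.per_trait_effect_prob is not None and not (
                0.0 <= self.per_trait_effect_prob <= 1.0):
            raise ValueError("per_trait_effect_prob must lie in [0, 1]")
        if any(cv <= 0 for cv in self.baseline_cvs.values()):
            raise ValueError("all baseline CVs must be > 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2 for testable traits")
        if self.n_replicates_wildtype < 2:
            raise ValueError("n_replicates_wildtype must be >= 2")
        if self.n_strains < 2:
            raise ValueError("need at least wild type plus one mutant")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")


@dataclass
class GroundTruth:
    """Planted truth accompanying a simulated data set."""

    affected: pd.DataFrame            # strains x traits, bool
    planted_shifts: pd.DataFrame      # strains x traits, trait units
    strain_groups: pd.Series          # planted cluster label per strain
    expression_clusters: pd.Series | None = None   # planted label per gene

    def to_json(self, path) -> None:
        payload = {
            "affected": {s: self.affected.loc[s].astype(bool).to_dict()
                         for s in self.affected.index},
            "planted_shifts": {s: self.planted_shifts.loc[s].to_dict()
                               for s in self.planted_shifts.index},
            "strain_groups": self.strain_groups.astype(int).to_dict(),
            "expression_clusters": (
                None if self.expression_clusters is None
                else self.expression_clusters.astype(int).to_dict()),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        affected = pd.DataFrame(payload["affected"]).T.astype(bool)
        shifts = pd.DataFrame(payload["planted_shifts"]).T
        groups = pd.Series(payload["strain_groups"], dtype=int)
        expr = payload.get("expression_clusters")
        return cls(affected, shifts[affected.columns], groups,
                   None if expr is None else pd.Series(expr, dtype=int))


def _effect_cut(effect_fraction: float, corr: np.ndarray,
                n_calib: int = 20000) -> float:
    """Two-sided latent cut so that P(any |z_t| > cut) = effect_fraction.

    Solved by Monte Carlo on the copula itself (fixed internal seed, so the
    cut is a deterministic function of the configuration): the cut is the
    (1 - f) quantile of max_t |z_t| over a calibration sample. Positive trait
    correlation concentrates exceedances in fewer strains, so this sits well
    below the independence-approximation cut.
    """
    if effect_fraction <= 0.0:
        return np.inf
    if effect_fraction >= 1.0:
        return 0.0
    rng = np.random.default_rng(np.random.SeedSequence(202406))
    sample = rng.multivariate_normal(
        np.zeros(corr.shape[0]), corr, size=n_calib, method="svd")
    max_abs = np.abs(sample).max(axis=1)
    return float(np.quantile(max_abs, 1.0 - effect_fraction))


def _group_patterns(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.n_groups == 4 and tuple(config.trait_names) == TRAITS:
        return default_group_patterns()
    # generic deterministic patterns: random signed directions with one
    # all-zero (wild-type-like) group
    pat = rng.choice([-1.0, 0.0, 1.0], size=(config.n_groups, len(config.trait_names)))
    pat[min(2, config.n_groups - 1), :] = 0.0
    return pat


def simulate_trait_table(
    config: SimulationConfig | None = None,
) -> tuple[TraitTable, GroundTruth]:
    """Simulate the replicate-level trait table plus its planted truth.

    Deterministic for a fixed ``config.rng_seed``. Raises ``ValueError`` for
    invalid configurations (e.g. a non-PSD trait correlation).
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    traits = list(config.trait_names)
    n_traits = len(traits)
    n_mut = config.n_strains - 1
    mutants = [f"mut_{i:04d}" for i in range(1, n_mut + 1)]
    strains = [WILDTYPE] + mutants

    means = np.array([config.baseline_means[t] for t in traits])
    sds = np.array([config.baseline_cvs[t] * config.baseline_means[t]
                    for t in traits])

    # latent copula draws (mutants only)
    z = rng.multivariate_normal(
        np.zeros(n_traits), np.asarray(config.trait_correlation, float),
        size=n_mut, method="svd")

    if config.per_trait_effect_prob is not None:
        p = config.per_trait_effect_prob
        cut = (np.inf if p <= 0
               else 0.0 if p >= 1
               else float(sps.norm.ppf(1.0 - p / 2.0)))
    else:
        cut = _effect_cut(config.effect_fraction,
                          np.asarray(config.trait_correlation, float))
    copula_affected = np.abs(z) > cut

    patterns = _group_patterns(config, rng)
    zero_group = int(np.argmin(np.abs(patterns).sum(axis=1)))
    groups_mut = rng.integers(0, config.n_groups, size=n_mut)

    shifts = (config.effect_size_sd * sds[None, :] * z * copula_affected
              + config.group_separation_sd * sds[None, :] * patterns[groups_mut])
    group_affected = np.abs(config.group_separation_sd * patterns[groups_mut]) > 0
    affected = copula_affected | group_affected

    # wild type: no effects, wild-type-like group
    affected_all = np.vstack([np.zeros(n_traits, bool), affected])
    shifts_all = np.vstack([np.zeros(n_traits), shifts])
    groups_all = np.concatenate([[zero_group], groups_mut])

    rows: list[tuple[str, str, int, float]] = []
    for si, strain in enumerate(strains):
        n_rep = (config.n_replicates_wildtype if strain == WILDTYPE
                 else config.n_replicates)
        for ti, trait in enumerate(traits):
            loc = means[ti] + shifts_all[si, ti]
            if trait == "count":
                lam = max(loc, 0.0)
                rows.append((strain, trait, 1, float(rng.poisson(lam))))
            elif trait == "timing":
                level = loc + rng.normal(0.0, sds[ti])
                level = int(np.clip(np.rint(level), 1, 5))
                rows.append((strain, trait, 1, float(level)))
            else:
                vals = loc + rng.normal(0.0, sds[ti], size=n_rep)
                if trait == "sporulation":
                    vals = np.maximum(vals, 0.0)
                rows.extend(
                    (strain, trait, r + 1, float(v))
                    for r, v in enumerate(vals))

    df = pd.DataFrame(rows, columns=["strain", "trait", "replicate", "value"])
    table = TraitTable(df, wildtype=WILDTYPE,
                       replicate_traits=tuple(t for t in traits
                                              if t in REPLICATE_TRAITS))
    truth = GroundTruth(
        affected=pd.DataFrame(affected_all, index=strains, columns=traits),
        planted_shifts=pd.DataFrame(shifts_all, index=strains, columns=traits),
        strain_groups=pd.Series(groups_all, index=strains, dtype=int),
    )
    return table, truth


# ---------------------------------------------------------------------------
# development-image simulation
# ---------------------------------------------------------------------------

@dataclass
class Blob:
    """Elliptical aggregate: center (row, col), semi-axes, orientation, intensity."""

    center: tuple[float, float]
    axes: tuple[float, float]
    orientation: float = 0.0
    intensity: float = 80.0


@dataclass
class ImageSpec:
    """Parameters for one synthetic brightfield development image."""

    width: int = 512
    height: int = 512
    background_level: float = 200.0
    blobs: list[Blob] = field(default_factory=list)
    noise_sd: float = 3.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.width < 2 or self.height < 2:
            raise ValueError("image must be at least 2x2")
        for b in self.blobs:
            if min(b.axes) <= 0:
                raise ValueError(f"zero-area blob rejected: {b}")
            if self.noise_sd > 0 and abs(b.intensity - self.background_level) <= 2 * self.noise_sd:
                raise ValueError(
                    "blob intensity must differ from background by more than "
                    f"2*noise_sd for separability: {b}")


def simulate_development_image(spec: ImageSpec):
    """Rasterize an image of elliptical aggregates plus exact ground truth.

    Returns ``(image, truth)`` where ``image`` is an 8-bit grayscale array and
    ``truth`` an :class:`myxphen.images.AggregateSet` whose per-blob area,
    perimeter, centroid and mean intensity are computed from the *rasterized*
    mask (so downstream recovery can be checked exactly), with blobs clipped
    at the frame flagged ``touches_edge``.
    """
    from skimage.draw import ellipse as draw_ellipse

    from .images import AggregateRecord, AggregateSet, _mask_measurements

    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    shape = (spec.height, spec.width)
    canvas = np.full(shape, float(spec.background_level))
    records: list[AggregateRecord] = []
    blob_masks = []
    for b in spec.blobs:
        rr, cc = draw_ellipse(b.center[0], b.center[1], b.axes[0], b.axes[1],
                              shape=shape, rotation=b.orientation)
        if rr.size == 0:
            raise ValueError(f"blob rasterizes to zero pixels: {b}")
        mask = np.zeros(shape, bool)
        mask[rr, cc] = True
        canvas[mask] = b.intensity
        blob_masks.append(mask)

    for label, (b, mask) in enumerate(zip(spec.blobs, blob_masks), start=1):
        area, perim, centroid, mean_gray, touches = _mask_measurements(
            mask, canvas)
        # clipping at the frame also counts as edge overlap
        rmax, cmax = shape[0] - 1, shape[1] - 1
        half = max(b.axes)
        clipped = (b.center[0] - half < 0 or b.center[1] - half < 0
                   or b.center[0] + half > rmax or b.center[1] + half > cmax)
        records.append(AggregateRecord(
            label=label, area=area, perimeter=perim,
            circularity=min(1.0, 4.0 * np.pi * area / perim**2) if perim > 0 else 1.0,
            mean_gray=mean_gray, centroid=centroid,
            touches_edge=bool(touches or clipped)))

    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd, size=shape)
    image = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    truth = AggregateSet(records=records, image_id="synthetic",
                         threshold_used=None, crop_region=None)
    return image, truth


def random_image_spec(
    rng: np.random.Generator,
    n_blobs: int | tuple[int, int] = (5, 15),
    width: int = 512,
    height: int = 512,
    min_area: float = 250.0,
    noise_sd: float = 3.0,
    margin: int = 25,
) -> ImageSpec:
    """Draw a random, non-overlapping, interior-blob image specification.

    Blobs are placed by rejection sampling with all continuous ellipses at
    least ``margin`` pixels from the frame and mutually separated, and sized
    so every rasterized blob exceeds ``min_area`` pixels (default comfortably
    above the 200-px analysis filter).
    """
    if isinstance(n_blobs, tuple):
        n_blobs = int(rng.integers(n_blobs[0], n_blobs[1] + 1))
    blobs: list[Blob] = []
    attempts = 0
    while len(blobs) < n_blobs:
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("could not place non-overlapping blobs")
        a = rng.uniform(10.0, 22.0)
        b = rng.uniform(0.75, 1.0) * a
        if np.pi * a * b < min_area * 1.15:
            continue
        r = rng.uniform(margin + a, height - 1 - margin - a)
        c = rng.uniform(margin + a, width - 1 - margin - a)
        if any(np.hypot(r - o.center[0], c - o.center[1])
               < (max(o.axes) + a + 4) for o in blobs):
            continue
        blobs.append(Blob(center=(r, c), axes=(a, b),
                          orientation=rng.uniform(0, np.pi),
                          intensity=rng.uniform(60.0, 110.0)))
    return ImageSpec(width=width, height=height, blobs=blobs,
                     noise_sd=noise_sd,
                     rng_seed=int(rng.integers(0, 2**31 - 1)))


# ---------------------------------------------------------------------------
# expression-matrix simulation
# ---------------------------------------------------------------------------

#: default developmental time course, hours post-starvation
DEFAULT_TIMEPOINTS: tuple[float, ...] = (0, 3, 6, 9, 12, 15, 18, 24)


def default_cluster_profiles(
    timepoints=DEFAULT_TIMEPOINTS,
) -> dict[str, np.ndarray]:
    """Four temporal archetypes of developmental expression.

    MA1: induced between the 12th and 24th hour; MA2: mostly silent (low,
    slowly decaying); MA3: activated early (peak in the 2nd-9th hour);
    MA4: nearly constitutively expressed (high, gently rising).
    """
    t = np.asarray(timepoints, dtype=float)
    return {
        "MA1": 2.0 / (1.0 + np.exp(-(t - 14.0) / 1.5)),
        "MA2": -1.0 - 0.04 * t,
        "MA3": 2.0 * np.exp(-((t - 6.0) ** 2) / (2 * 2.5**2)),
        "MA4": 1.0 + 0.04 * t,
    }


def simulate_expression_matrix(
    n_genes: int = 180,
    timepoints=DEFAULT_TIMEPOINTS,
    cluster_profiles: dict[str, np.ndarray] | None = None,
    noise_sd: float = 0.3,
    rng_seed: int = 0,
    gene_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a genes x timepoints log-expression matrix with planted clusters.

    Each gene's profile equals its cluster's temporal mean curve plus i.i.d.
    Gaussian noise. Returns the matrix (hour-labelled columns) and the planted
    per-gene cluster labels.
    """
    t = np.asarray(timepoints, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 timepoints")
    profiles = cluster_profiles or default_cluster_profiles(t)
    names = list(profiles)
    if len(names) < 2:
        raise ValueError("need at least 2 cluster profiles")
    if n_genes < len(names):
        raise ValueError(
            f"fewer genes ({n_genes}) than clusters ({len(names)})")
    for name, curve in profiles.items():
        if np.asarray(curve).shape != t.shape:
            raise ValueError(f"profile {name!r} length != number of timepoints")

    rng = np.random.default_rng(rng_seed)
    labels = np.array([names[i % len(names)] for i in range(n_genes)])
    rng.shuffle(labels)
    curves = np.stack([np.asarray(profiles[l], float) for l in labels])
    values = curves + rng.normal(0.0, noise_sd, size=curves.shape)

    if gene_ids is None:
        gene_ids = [f"gene_{i:04d}" for i in range(1, n_genes + 1)]
    cols = [f"{h:g}h" for h in t]
    matrix = pd.DataFrame(values, index=gene_ids, columns=cols)
    matrix.index.name = "gene"
    return matrix, pd.Series(labels, index=gene_ids, name="cluster")
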