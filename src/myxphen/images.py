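"""Aggregate (fruiting-body) trait extraction from brightfield images.

Pipeline per image: take a 25%-area corner crop that avoids the spot edge,
auto-threshold with the Rényi-entropy criterion, label connected components
(8-connectivity), drop components below 200 px or touching any image border,
and summarize count, area, grayness (mean original intensity, 0-255, higher =
lighter) and circularity (4*pi*area/perimeter^2, capped at 1 because the
crack-boundary perimeter estimator can push rasterized disks slightly above
the continuous isoperimetric bound).

The threshold follows the three-order Rényi-entropy rule of Sahoo, Wilkins &
Yeager as propagated by the common ImageJ auto-threshold plugin lineage:
candidate thresholds maximizing the summed background/foreground Rényi
entropies are found for alpha -> 1 (Shannon/Kapur), alpha = 0.5 and alpha = 2,
then blended with data-dependent weights. One deliberate deviation from that
lineage: on plateaus where several candidates share the maximal criterion
value, the plateau *midpoint* is returned (the plugin keeps the first), so a
two-level histogram yields a threshold strictly between the levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

__all__ = [
    "AggregateRecord",
    "AggregateSet",
    "crop_quarter",
    "renyi_entropy_threshold",
    "renyi_partial_thresholds",
    "segment_aggregates",
    "circularity",
    "summarize_image_traits",
]

CORNERS = ("NW", "NE", "SW", "SE")


@dataclass
class AggregateRecord:
    """One segmented aggregate and its morphometric features."""

    label: int
    area: float              # pixels
    perimeter: float         # crack-boundary estimate, pixels
    circularity: float       # 4*pi*A/P^2, capped at 1
    mean_gray: float         # mean original intensity over the mask, 0-255
    centroid: tuple[float, float]   # (row, col), 0-based pixel centers
    touches_edge: bool


@dataclass
class AggregateSet:
    """Per-image collection of aggregates plus segmentation provenance."""

    records: list[AggregateRecord] = field(default_factory=list)
    image_id: str = ""
    threshold_used: float | None = None
    crop_region: tuple[int, int, int, int] | None = None  # (r0, c0, r1, c1)

    @property
    def count(self) -> int:
        return len(self.records)

    def areas(self) -> np.ndarray:
        return np.array([r.area for r in self.records], float)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "label": r.label,
                    "area": r.area,
                    "perimeter": r.perimeter,
                    "circularity": r.circularity,
                    "mean_gray": r.mean_gray,
                    "centroid_row": r.centroid[0],
                    "centroid_col": r.centroid[1],
                    "touches_edge": r.touches_edge,
                }
                for r in self.records
            ]
        )


def crop_quarter(image: np.ndarray, corner: str = "NW") -> np.ndarray:
    """Return the 25%-area sub-image (half width x half height) at ``corner``.

    Odd dimensions floor-divide, so a 101x101 image yields a 50x50 crop.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] < 2 or image.shape[1] < 2:
        raise ValueError("image must be 2-D and at least 2x2")
    if corner not in CORNERS:
        raise ValueError(f"corner must be one of {CORNERS}")
    h2, w2 = image.shape[0] // 2, image.shape[1] // 2
    r0 = 0 if corner[0] == "N" else image.shape[0] - h2
    c0 = 0 if corner[1] == "W" else image.shape[1] - w2
    return image[r0:r0 + h2, c0:c0 + w2]


# ---------------------------------------------------------------------------
# Renyi-entropy auto-threshold
# ---------------------------------------------------------------------------

_EPS = 2.220446049250313e-16


def _plateau_mid_argmax(values: np.ndarray, valid: np.ndarray) -> int:
    vals = np.where(valid, values, -np.inf)
    best = vals.max()
    ties = np.flatnonzero(vals >= best - 1e-12)
    return int(ties[(len(ties) - 1) // 2])


def _renyi_criterion(norm_histo: np.ndarray, alpha: float) -> np.ndarray:
    """Total Rényi entropy of the background/foreground split per threshold t.

    Background = bins 0..t, foreground = bins t+1..255; bins with zero mass
    contribute nothing. Returns -inf where either side has zero probability.
    """
    p = norm_histo
    P1 = np.cumsum(p)
    P2 = 1.0 - P1
    n = p.size
    crit = np.full(n, -np.inf)
    for t in range(n):
        if P1[t] < _EPS or P2[t] < _EPS:
            continue
        back = p[: t + 1] / P1[t]
        fore = p[t + 1:] / P2[t]
        back = back[back > 0]
        fore = fore[fore > 0]
        if back.size == 0 or fore.size == 0:
            continue
        if abs(alpha - 1.0) < 1e-12:
            crit[t] = -(back * np.log(back)).sum() - (fore * np.log(fore)).sum()
        else:
            sb = (back ** alpha).sum()
            sf = (fore ** alpha).sum()
            if sb <= 0 or sf <= 0:
                continue
            crit[t] = np.log(sb * sf) / (1.0 - alpha)
    return crit


def renyi_partial_thresholds(histogram: np.ndarray) -> tuple[int, int, int]:
    """Criterion-maximizing thresholds for alpha = 0.5, 1 and 2."""
    hist = np.asarray(histogram, dtype=float)
    total = hist.sum()
    if total <= 0 or (hist > 0).sum() < 2:
        raise ValueError("histogram needs at least two occupied levels")
    norm = hist / total
    P1 = np.cumsum(norm)
    valid = (P1 >= _EPS) & (1.0 - P1 >= _EPS)
    return tuple(
        _plateau_mid_argmax(_renyi_criterion(norm, a), valid)
        for a in (0.5, 1.0, 2.0)
    )


def renyi_entropy_threshold(
    image: np.ndarray | None = None, *, histogram: np.ndarray | None = None
) -> int:
    """8-bit threshold from the three-order Rényi-entropy combination rule.

    Depends only on the intensity histogram (hence invariant under any pixel
    permutation) and is deterministic. Raises ``ValueError`` for a constant
    image, which cannot be thresholded.
    """
    if histogram is None:
        if image is None:
            raise ValueError("provide an image or a histogram")
        img = np.asarray(image)
        if img.dtype != np.uint8:
            img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        histogram = np.bincount(img.ravel(), minlength=256)
    hist = np.asarray(histogram, dtype=float)
    t1, t2, t3 = sorted(renyi_partial_thresholds(hist))

    norm = hist / hist.sum()
    P1 = np.cumsum(norm)
    P2 = 1.0 - P1

    # data-dependent blending weights (Sahoo et al. combination rule)
    if abs(t1 - t2) <= 5:
        if abs(t2 - t3) <= 5:
            beta = (1, 2, 1)
        else:
            beta = (0, 1, 3)
    else:
        if abs(t2 - t3) <= 5:
            beta = (3, 1, 0)
        else:
            beta = (1, 2, 1)
    omega = P1[t3] - P1[t1]
    threshold = (
        t1 * (P1[t1] + 0.25 * omega * beta[0])
        + 0.25 * t2 * omega * beta[1]
        + t3 * (P2[t3] + 0.25 * omega * beta[2])
    )
    return int(threshold)


# ---------------------------------------------------------------------------
# segmentation and per-aggregate features
# ---------------------------------------------------------------------------

def circularity(area: float, perimeter: float) -> float:
    """Isoperimetric ratio 4*pi*area/perimeter^2, capped at 1.0."""
    if perimeter <= 0:
        raise ValueError("perimeter must be > 0")
    return min(1.0, 4.0 * np.pi * float(area) / float(perimeter) ** 2)


def _mask_measurements(mask: np.ndarray, intensity: np.ndarray):
    """Area, crack-boundary perimeter, centroid, mean intensity, edge flag."""
    props = measure.regionprops(mask.astype(np.uint8),
                                intensity_image=intensity)[0]
    area = float(props.area)
    perim = float(props.perimeter)
    centroid = tuple(float(x) for x in props.centroid)
    mean_gray = float(props.intensity_mean)
    rows, cols = np.nonzero(mask)
    touches = bool(
        rows.min() == 0 or cols.min() == 0
        or rows.max() == mask.shape[0] - 1 or cols.max() == mask.shape[1] - 1
    )
    return area, perim, centroid, mean_gray, touches


def segment_aggregates(
    image: np.ndarray,
    threshold: float | None = None,
    min_area: int = 200,
    dark_aggregates: bool = True,
    connectivity: int = 2,
    mask_override: np.ndarray | None = None,
    image_id: str = "",
) -> AggregateSet:
    """Segment aggregates and filter by size and edge contact.

    Foreground is ``image <= threshold`` for dark aggregates (the default,
    aggregates being more opaque than the agar background) or ``image >=
    threshold`` otherwise; ``mask_override`` replaces the thresholded mask
    entirely (the non-interactive stand-in for manual correction). Components
    smaller than ``min_area`` pixels or touching any border are excluded.
    ``mean_gray`` is always measured on the original, pre-threshold
    intensities.
    """
    image = np.asarray(image)
    if mask_override is not None:
        mask = np.asarray(mask_override, bool)
        if mask.shape != image.shape:
            raise ValueError("mask_override shape must match image")
    else:
        if threshold is None:
            threshold = renyi_entropy_threshold(image)
        lo, hi = image.min(), image.max()
        if not (lo <= threshold <= hi):
            raise ValueError(
                f"threshold {threshold} outside intensity range [{lo}, {hi}]")
        mask = image <= threshold if dark_aggregates else image >= threshold

    labels = measure.label(mask, connectivity=connectivity)
    records: list[AggregateRecord] = []
    out_label = 0
    for props in measure.regionprops(labels, intensity_image=image):
        minr, minc, maxr, maxc = props.bbox
        touches = (minr == 0 or minc == 0
                   or maxr == image.shape[0] or maxc == image.shape[1])
        if props.area < min_area or touches:
            continue
        out_label += 1
        perim = float(props.perimeter)
        # degenerate (single-pixel) components have zero crack perimeter;
        # treat them as fully compact rather than erroring
        records.append(AggregateRecord(
            label=out_label,
            area=float(props.area),
            perimeter=perim,
            circularity=circularity(props.area, perim) if perim > 0 else 1.0,
            mean_gray=float(props.intensity_mean),
            centroid=tuple(float(x) for x in props.centroid),
            touches_edge=False,
        ))
    return AggregateSet(records=records, image_id=image_id,
                        threshold_used=None if mask_override is not None
                        else float(threshold),
                        crop_region=None)


def summarize_image_traits(agg: AggregateSet) -> dict[str, float]:
    """Per-image summary: count plus mean/SD of area, grayness, circularity.

    Sample SDs; means and SDs are NaN when undefined (count 0, resp. < 2).
    """
    out: dict[str, float] = {"count": float(agg.count)}
    for name, vals in (
        ("area", [r.area for r in agg.records]),
        ("grayness", [r.mean_gray for r in agg.records]),
        ("circularity", [r.circularity for r in agg.records]),
    ):
        arr = np.asarray(vals, float)
        out[f"{name}_mean"] = float(arr.mean()) if arr.size else float("nan")
        out[f"{name}_sd"] = (float(arr.std(ddof=1)) if arr.size >= 2
                             else float("nan"))
    return out
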