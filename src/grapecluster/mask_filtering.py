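"""Reduce raw instance masks to true berry masks.

Three stages, in pipeline order:

1. overlap — masks spanning two or more berries are detected through
   containment (intersection over the smaller mask) against their child
   masks and removed;
2. geometric — objects whose area, aspect ratio, perimeter-to-area ratio
   or distance from the cluster falls outside median-relative bounds
   (reference circle, clamp, background stains, rachis bits) are removed;
3. EFD+PCA — remaining non-berry outlines are removed by iterated
   principal-component outlier rejection on elliptic Fourier
   coefficients, recomputing harmonics and components each round.

Every removal is logged with its stage and reason; the report counts
always partition the input.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

from .mask_io import MaskRecord, mask_to_contour
from .shape_features import (
    ColorSummary,
    EFDSet,
    ShapeMetrics,
    contour_metrics,
    efd_coefficients,
    median_color,
    smooth_contour,
)

__all__ = [
    "FilterConfig",
    "FilterReport",
    "BerryRecord",
    "pairwise_overlap",
    "remove_multiberry_masks",
    "geometric_filter",
    "efd_pca_outlier_removal",
    "detect_reference_circle",
    "run_filter_pipeline",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the three filtering stages.

    Geometric bounds are multiples of per-image medians so the filter is
    scale-free; absolute fallbacks apply when a scene has fewer than three
    masks and medians are meaningless.
    """

    containment_threshold: float = 0.8
    min_children: int = 2
    area_bounds: tuple[float, float] = (0.2, 5.0)  # x median berry area
    aspect_min: float = 0.4
    perimeter_area_max: float = 3.0  # x median P/A ratio
    max_centroid_distance: float = 2.0  # x cluster radius
    pca_rounds: int = 5
    pca_n_components: int = 10
    pca_sd_threshold: float = 2.0
    n_harmonics: int = 10
    fallback_area_bounds: tuple[float, float] = (30.0, 1e6)  # px^2
    fallback_perimeter_area_max: float = 1.0  # 1/px
    min_circularity: float = 0.9  # reference-circle detection


@dataclass
class FilterReport:
    n_input: int = 0
    n_removed_overlap: int = 0
    n_removed_geometric: int = 0
    n_removed_efd_pca: int = 0
    n_kept: int = 0
    removals: list[tuple[str, str, str]] = field(default_factory=list)

    def check_conservation(self) -> None:
        total = (
            self.n_kept
            + self.n_removed_overlap
            + self.n_removed_geometric
            + self.n_removed_efd_pca
        )
        if total != self.n_input:
            raise AssertionError(
                f"filter bookkeeping broken: {self.n_input} != {total}"
            )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "n_input": self.n_input,
                "n_removed_overlap": self.n_removed_overlap,
                "n_removed_geometric": self.n_removed_geometric,
                "n_removed_efd_pca": self.n_removed_efd_pca,
                "n_kept": self.n_kept,
                "removals": [list(r) for r in self.removals],
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


@dataclass
class BerryRecord:
    """A mask that survived filtering, with its phenotype features."""

    mask_id: str
    contour: np.ndarray  # crack-edge contour, px
    smooth: np.ndarray  # resampled/smoothed contour for metric use
    metrics: ShapeMetrics
    efd: EFDSet | None = None
    color: ColorSummary | None = None
    image_id: str | None = None
    cluster_id: str | None = None
    angle: int | None = None

    @property
    def centroid(self) -> tuple[float, float]:
        return self.metrics.centroid


def pairwise_overlap(mask_a: np.ndarray, mask_b: np.ndarray) -> tuple[float, float]:
    """IoU and containment-of-smaller for two binary masks on one grid."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 or nb == 0:
        raise ValueError("empty mask")
    inter = int((a & b).sum())
    union = na + nb - inter
    return inter / union, inter / min(na, nb)


def _bbox_intersects(b1, b2) -> bool:
    x1, y1, w1, h1 = b1
    x2, y2, w2, h2 = b2
    return x1 < x2 + w2 and x2 < x1 + w1 and y1 < y2 + h2 and y2 < y1 + h1


def remove_multiberry_masks(
    records: list[MaskRecord], config: FilterConfig = FilterConfig()
) -> tuple[list[MaskRecord], list[tuple[MaskRecord, str]]]:
    """Remove masks that cover two or more individually masked berries.

    A mask is removed iff at least ``min_children`` smaller masks are each
    mostly contained in it (containment >= threshold).  The child ids are
    recorded as the removal reason.
    """
    if not records:
        return [], []
    grids = [r.decode() for r in records]
    areas = [int(g.sum()) for g in grids]
    removed: list[tuple[MaskRecord, str]] = []
    kept: list[MaskRecord] = []
    for i, rec in enumerate(records):
        children = []
        for j, other in enumerate(records):
            if i == j or areas[j] >= areas[i]:
                continue
            if not _bbox_intersects(rec.bbox, other.bbox):
                continue
            inter = int((grids[i] & grids[j]).sum())
            if inter / areas[j] >= config.containment_threshold:
                children.append(other.mask_id)
        if len(children) >= config.min_children:
            removed.append((rec, "children:" + ",".join(children)))
        else:
            kept.append(rec)
    return kept, removed


def geometric_filter(
    records: list[tuple[MaskRecord, ShapeMetrics]],
    config: FilterConfig = FilterConfig(),
    cluster_centroid: tuple[float, float] | None = None,
) -> tuple[list[tuple[MaskRecord, ShapeMetrics]], list[tuple[MaskRecord, str]]]:
    """Median-relative filters on area, aspect, P/A ratio and position.

    Size and shape bounds are applied first; the position filter then
    derives the cluster centre and per-axis spread robustly (median and
    MAD of centroids) from the size/shape survivors only, so large
    off-cluster objects cannot drag the estimate.  A record is
    off-cluster when its centroid deviation on either axis exceeds
    ``max_centroid_distance`` robust standard deviations.
    """
    if not records:
        return [], []
    metrics = [m for _, m in records]
    if len(records) >= 3:
        med_area = float(np.median([m.area for m in metrics]))
        med_pa = float(np.median([m.perimeter_area_ratio for m in metrics]))
        lo, hi = config.area_bounds[0] * med_area, config.area_bounds[1] * med_area
        pa_max = config.perimeter_area_max * med_pa
    else:
        warnings.warn(
            "fewer than 3 masks: using absolute fallback bounds", stacklevel=2
        )
        lo, hi = config.fallback_area_bounds
        pa_max = config.fallback_perimeter_area_max
    kept, removed = [], []
    for rec, m in records:
        if not lo <= m.area <= hi:
            removed.append((rec, "area"))
        elif m.aspect_ratio < config.aspect_min:
            removed.append((rec, "aspect"))
        elif m.perimeter_area_ratio > pa_max:
            removed.append((rec, "perimeter_area"))
        else:
            kept.append((rec, m))
    if len(kept) >= 3:
        cent = np.array([m.centroid for _, m in kept])
        centre = (
            np.median(cent, axis=0)
            if cluster_centroid is None
            else np.asarray(cluster_centroid, dtype=float)
        )
        dev = np.abs(cent - centre)
        scale = np.maximum(1.4826 * np.median(dev, axis=0), 1.0)
        far = (dev > config.max_centroid_distance * scale).any(axis=1)
        still, dropped = [], []
        for pair, is_far in zip(kept, far):
            (dropped if is_far else still).append(pair)
        removed += [(rec, "distance") for rec, _ in dropped]
        kept = still
    return kept, removed


def efd_pca_outlier_removal(
    records: list[tuple[MaskRecord, np.ndarray]],
    config: FilterConfig = FilterConfig(),
) -> tuple[
    list[tuple[MaskRecord, np.ndarray]],
    list[tuple[MaskRecord, str]],
    list[int],
]:
    """Iterated shape-outlier rejection on EFD coefficients.

    Each round recomputes elliptic Fourier harmonics (translation, scale
    and rotation normalized — a berry outline's orientation is not a
    berry/non-berry signal) on the surviving outlines, runs PCA on the
    flattened coefficients, and removes every outline whose Euclidean
    distance from the centroid, in the score space of the first
    ``pca_n_components`` components, exceeds ``pca_sd_threshold`` times
    the RMS spread of that score cloud (the square root of the summed
    component variances).  True berries form a tight, bounded shape
    cloud, so they stay well inside the threshold, while rachis bits and
    other non-berry outlines sit far outside and inflate no more than
    one round's spread.  Stops early when a round removes nothing; a
    zero-variance cloud (all shapes identical) removes nothing.  Returns
    (kept, removed, kept-count per round).
    """
    kept = list(records)
    removed: list[tuple[MaskRecord, str]] = []
    round_log: list[int] = []
    if len(kept) < config.pca_n_components + 2:
        warnings.warn(
            "too few masks for EFD+PCA outlier removal; stage skipped",
            stacklevel=2,
        )
        return kept, removed, round_log
    for rnd in range(config.pca_rounds):
        feats = np.array(
            [
                efd_coefficients(
                    contour,
                    config.n_harmonics,
                    normalize_scale=True,
                    normalize_rotation=True,
                ).coefficients.ravel()
                for _, contour in kept
            ]
        )
        n_comp = min(config.pca_n_components, len(kept) - 1, feats.shape[1])
        pca = PCA(n_components=n_comp, svd_solver="full").fit(feats)
        scores = pca.transform(feats)
        rms = float(np.sqrt(pca.explained_variance_.sum()))
        if rms < 1e-9:  # zero-variance guard
            round_log.append(len(kept))
            break
        dist = np.linalg.norm(scores, axis=1)
        out = dist > config.pca_sd_threshold * rms
        if not out.any():
            round_log.append(len(kept))
            break
        for (rec, _), is_out in zip(list(kept), out):
            if is_out:
                removed.append((rec, f"efd_pca_round_{rnd + 1}"))
        kept = [kc for kc, is_out in zip(kept, out) if not is_out]
        round_log.append(len(kept))
        if len(kept) < config.pca_n_components + 2:
            break
    return kept, removed, round_log


def detect_reference_circle(
    removed_records: list[tuple[MaskRecord, ShapeMetrics]],
    known_diameter_mm: float,
    min_circularity: float = 0.9,
) -> float | None:
    """Find the size-reference circle among removed objects.

    The most circular large removed object (isoperimetric ratio >=
    ``min_circularity``) is taken as the reference; the returned scale is
    known diameter / Feret diameter in mm/px.  Returns None with a warning
    when no candidate qualifies, in which case analysis proceeds in px.
    """
    if known_diameter_mm <= 0:
        raise ValueError("known_diameter_mm must be positive")
    candidates = [m for _, m in removed_records if m.circularity >= min_circularity]
    best = max(candidates, key=lambda m: (m.circularity, m.area), default=None)
    if best is None:
        warnings.warn(
            "no circular reference object found; scale left unset", stacklevel=2
        )
        return None
    return known_diameter_mm / best.length


def run_filter_pipeline(
    records: list[MaskRecord],
    config: FilterConfig = FilterConfig(),
    image: np.ndarray | None = None,
    known_diameter_mm: float | None = None,
    scale_mm_per_px: float | None = None,
) -> tuple[list[BerryRecord], FilterReport, float | None]:
    """Full overlap -> geometric -> EFD+PCA filtering of one image.

    When ``known_diameter_mm`` is given the reference circle is sought
    among the removed objects and used to convert metrics to millimetres;
    an explicit ``scale_mm_per_px`` overrides detection.  Returns the kept
    berries (with geometry, EFD and, if an image is supplied, median
    color), the bookkeeping report, and the scale actually used.
    """
    report = FilterReport(n_input=len(records))

    kept1, rem_overlap = remove_multiberry_masks(records, config)
    report.n_removed_overlap = len(rem_overlap)
    report.removals += [(r.mask_id, "overlap", why) for r, why in rem_overlap]

    with_metrics: list[tuple[MaskRecord, ShapeMetrics]] = []
    contours: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for rec in kept1:
        grid = rec.decode()
        contour = mask_to_contour(grid)
        smooth = smooth_contour(contour)
        m = contour_metrics(smooth)
        # exact pixel area rather than the smoothed polygon's
        m = ShapeMetrics(
            area=float(grid.sum()),
            perimeter=m.perimeter,
            length=m.length,
            width=m.width,
            aspect_ratio=m.aspect_ratio,
            centroid=m.centroid,
            perimeter_area_ratio=m.perimeter / float(grid.sum()),
        )
        contours[rec.mask_id] = (contour, smooth)
        with_metrics.append((rec, m))

    kept2, rem_geom = geometric_filter(with_metrics, config)
    report.n_removed_geometric = len(rem_geom)
    report.removals += [(r.mask_id, "geometric", why) for r, why in rem_geom]

    kept3, rem_pca, _ = efd_pca_outlier_removal(
        [(rec, contours[rec.mask_id][1]) for rec, _ in kept2], config
    )
    report.n_removed_efd_pca = len(rem_pca)
    report.removals += [(r.mask_id, "efd_pca", why) for r, why in rem_pca]

    scale = scale_mm_per_px
    if scale is None and known_diameter_mm is not None:
        removed_ids = {rr.mask_id for rr, _ in rem_geom}
        removed_with_metrics = [
            (rec, m) for (rec, m) in with_metrics if rec.mask_id in removed_ids
        ]
        scale = detect_reference_circle(
            removed_with_metrics, known_diameter_mm, config.min_circularity
        )

    metrics_by_id = {rec.mask_id: m for rec, m in with_metrics}
    berries: list[BerryRecord] = []
    for rec, _ in kept3:
        contour, smooth = contours[rec.mask_id]
        m = metrics_by_id[rec.mask_id]
        if scale is not None:
            m = ShapeMetrics(
                area=m.area,
                perimeter=m.perimeter,
                length=m.length,
                width=m.width,
                aspect_ratio=m.aspect_ratio,
                centroid=m.centroid,
                perimeter_area_ratio=m.perimeter_area_ratio,
                area_mm2=m.area * scale**2,
                perimeter_mm=m.perimeter * scale,
                length_mm=m.length * scale,
                width_mm=m.width * scale,
            )
        color = None
        if image is not None:
            color = median_color(rec.decode(), image)
        berries.append(
            BerryRecord(
                mask_id=rec.mask_id,
                contour=contour,
                smooth=smooth,
                metrics=m,
                efd=efd_coefficients(smooth, config.n_harmonics, normalize_scale=True),
                color=color,
                image_id=rec.image_id,
                cluster_id=rec.cluster_id,
                angle=rec.angle,
            )
        )
    report.n_kept = len(berries)
    report.check_conservation()
    return berries, report, scale
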