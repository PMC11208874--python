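"""Cluster-level architecture descriptors from berry masks.

A cluster view is summarized by (i) empirical cumulative distribution
profiles of berry centroid positions along the image axes, normalized to
[0, 100] (y runs peduncle to tip); (ii) a symmetry class derived from the
ECDF values at normalized coordinates 25/50/75; (iii) a concave hull of
the union of berry outlines, whose area, length (y extent), width
(x extent), perimeter and aspect describe overall cluster shape; (iv) the
compactness ratio, total berry area over hull area; and (v) a PCA of the
hull outlines' elliptic Fourier coefficients across clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPoint
from sklearn.decomposition import PCA

from .shape_features import efd_coefficients

__all__ = [
    "ECDFProfile",
    "HullShape",
    "ShapePCAResult",
    "ecdf_profile",
    "classify_symmetry",
    "concave_hull",
    "compactness",
    "shape_pca",
]

N_SAMPLES = 100  # ECDF sampling resolution on the [0, 100] axis


@dataclass(frozen=True)
class ECDFProfile:
    axis: str  # "x" or "y"
    normalized_coordinates: np.ndarray  # 100 values on [0, 100]
    cumulative_fraction: np.ndarray  # 100 values in [0, 1]
    quantile_at_25: float
    quantile_at_50: float
    quantile_at_75: float


@dataclass(frozen=True)
class HullShape:
    polygon: np.ndarray  # (N, 2) closed vertex list, first != last
    concavity: float
    area: float
    perimeter: float
    length: float  # y extent (clusters hang vertically)
    width: float  # x extent
    aspect_ratio: float  # width / length
    area_mm2: float | None = None


@dataclass(frozen=True)
class ShapePCAResult:
    scores: np.ndarray  # clusters x components
    explained_variance_fraction: np.ndarray
    loadings: np.ndarray  # components x EFD-coefficient space


def _centroids(berries) -> np.ndarray:
    """Accept an (N, 2) array or objects with a ``centroid`` attribute."""
    arr = np.asarray(
        [b.centroid if hasattr(b, "centroid") else b for b in berries], dtype=float
    )
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("berries must yield (x, y) centroids")
    return arr


def ecdf_profile(berries, axis: str = "y") -> ECDFProfile:
    """ECDF of berry positions along one axis, normalized to [0, 100].

    Positions are shifted to start at 0 and scaled so the largest is 100,
    then the ECDF is evaluated at 100 evenly spaced coordinates.  The
    recorded quantiles are the cumulative fractions at normalized
    coordinates exactly 25, 50 and 75.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    cent = _centroids(berries)
    if len(cent) < 2:
        raise ValueError("at least 2 berries required (scale undefined)")
    pos = cent[:, 0] if axis == "x" else cent[:, 1]
    pos = pos - pos.min()
    if pos.max() == 0:
        raise ValueError("all berries at the same position: scale undefined")
    pos = pos / pos.max() * 100.0
    pos.sort()
    coords = np.linspace(0.0, 100.0, N_SAMPLES)
    frac = np.searchsorted(pos, coords, side="right") / len(pos)
    q25, q50, q75 = (
        float(np.searchsorted(pos, q, side="right") / len(pos)) for q in (25, 50, 75)
    )
    return ECDFProfile(
        axis=axis,
        normalized_coordinates=coords,
        cumulative_fraction=frac,
        quantile_at_25=q25,
        quantile_at_50=q50,
        quantile_at_75=q75,
    )


def classify_symmetry(profile: ECDFProfile) -> str:
    """Coarse symmetry class from the ECDF quantiles.

    skew_left: mass piled at low coordinates (q25 > 0.3 and q75 > 0.8);
    skew_right: mass piled at high coordinates (q25 < 0.2 and q75 < 0.7);
    symmetric: q25 in [0.2, 0.3], q50 in [0.45, 0.55], q75 in [0.7, 0.8];
    otherwise "other".
    """
    q25, q50, q75 = (
        profile.quantile_at_25,
        profile.quantile_at_50,
        profile.quantile_at_75,
    )
    if q25 > 0.3 and q75 > 0.8:
        return "skew_left"
    if q25 < 0.2 and q75 < 0.7:
        return "skew_right"
    if 0.2 <= q25 <= 0.3 and 0.45 <= q50 <= 0.55 and 0.7 <= q75 <= 0.8:
        return "symmetric"
    return "other"


def concave_hull(
    berry_contours: Iterable[np.ndarray],
    concavity: float = 5.0,
    scale_mm_per_px: float | None = None,
) -> HullShape:
    """Concave hull of the union of berry outlines.

    ``concavity`` controls boundary detail: larger values give smoother,
    more convex hulls, with the convex hull in the limit; values near 1
    follow indentations (wing sinuses, shoulders) closely.  Internally the
    parameter is mapped monotonically onto the length-ratio of the GEOS
    concave-hull algorithm.  The hull always contains every input vertex.
    """
    if concavity <= 0:
        raise ValueError("concavity must be positive")
    pts = np.vstack([np.asarray(c, dtype=float) for c in berry_contours])
    if len(pts) < 3:
        raise ValueError("need at least 3 vertices")
    ratio = float(np.clip(1.0 - 1.0 / concavity, 0.0, 1.0))
    hull = shapely.concave_hull(MultiPoint(pts), ratio=ratio, allow_holes=False)
    if hull.geom_type != "Polygon" or hull.area <= 0:
        raise ValueError("degenerate (collinear) input: no polygonal hull")
    verts = np.asarray(hull.exterior.coords)[:-1]
    width = float(pts[:, 0].max() - pts[:, 0].min())
    length = float(pts[:, 1].max() - pts[:, 1].min())
    s = scale_mm_per_px
    return HullShape(
        polygon=verts,
        concavity=concavity,
        area=float(hull.area),
        perimeter=float(hull.length),
        length=length,
        width=width,
        aspect_ratio=width / length,
        area_mm2=None if s is None else hull.area * s**2,
    )


def compactness(berry_areas: Iterable[float], hull: HullShape) -> float:
    """Cluster compactness: total berry area over concave-hull area."""
    if hull.area <= 0:
        raise ValueError("hull has zero area")
    return float(np.sum(np.fromiter(berry_areas, dtype=float)) / hull.area)


def shape_pca(
    hulls: Sequence[HullShape | np.ndarray], n_harmonics: int = 10
) -> ShapePCAResult:
    """PCA of hull-outline elliptic Fourier coefficients across clusters.

    Outlines are translation- and scale-normalized but keep their
    orientation (clusters hang vertically, so orientation is meaningful
    and the first component reflects elongation/aspect).  Explained
    variance fractions sum to 1 over the returned components.
    """
    if len(hulls) < 3:
        raise ValueError("need at least 3 hulls")
    feats = []
    for h in hulls:
        outline = h.polygon if isinstance(h, HullShape) else np.asarray(h)
        efd = efd_coefficients(outline, n_harmonics, normalize_scale=True)
        feats.append(efd.coefficients.ravel())
    X = np.asarray(feats)
    if np.allclose(X.var(axis=0), 0.0):  # identical outlines
        k = min(len(X) - 1, X.shape[1])
        return ShapePCAResult(
            scores=np.zeros((len(X), k)),
            explained_variance_fraction=np.zeros(k),
            loadings=np.zeros((k, X.shape[1])),
        )
    pca = PCA(svd_solver="full").fit(X)
    scores = pca.transform(X)
    return ShapePCAResult(
        scores=scores,
        explained_variance_fraction=pca.explained_variance_ratio_,
        loadings=pca.components_,
    )
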