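"""Occlusion correction of visible-berry counts and sizes.

Roughly half the berries of a hanging cluster are hidden from any single
viewpoint, but the underestimation is linear, so a model
``y = beta0 + beta1 * x`` mapping the visible metric to the true metric
corrects it well.  For counts, the visible predictor is the maximum count
over the available view angles (a wing visible from one angle is hidden
from the next); for maximum berry area all views are pooled.  Model
quality is reported as adjusted R^2 and pooled k-fold cross-validated
R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CorrectionModel",
    "AngleSeries",
    "max_across_angles",
    "fit_linear_correction",
    "kfold_cv_r2",
    "predict_corrected",
    "angle_variation_stats",
]

ANGLES = (0, 90, 180, 270)


@dataclass
class CorrectionModel:
    beta0: float
    beta1: float
    adjusted_r2: float
    n: int
    target: str = "count"  # or "max_area"
    cv_r2: float | None = None

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta1": self.beta1,
            "adjusted_r2": self.adjusted_r2,
            "cv_r2": self.cv_r2,
            "n": self.n,
            "target": self.target,
        }


@dataclass
class AngleSeries:
    """Visible metrics for one cluster imaged at up to four angles."""

    cluster_id: str
    counts: dict[int, int] = field(default_factory=dict)
    max_area: dict[int, float] = field(default_factory=dict)

    def relative_change(self) -> dict[int, float]:
        """Per-angle change in count relative to the first (0 deg) view."""
        angles = sorted(self.counts)
        if not angles:
            return {}
        ref = self.counts[angles[0]]
        if ref == 0:
            raise ValueError(f"cluster {self.cluster_id}: zero count at first angle")
        return {a: (self.counts[a] - ref) / ref for a in angles}


def max_across_angles(series: AngleSeries) -> tuple[int | None, float | None]:
    """Element-wise maxima of count and max berry area over angles."""
    if not series.counts and not series.max_area:
        raise ValueError("no angle data")
    mc = max(series.counts.values()) if series.counts else None
    ma = max(series.max_area.values()) if series.max_area else None
    return mc, ma


def fit_linear_correction(
    x: np.ndarray, y: np.ndarray, target: str = "count"
) -> CorrectionModel:
    """Ordinary least squares y = beta0 + beta1*x in closed form."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or n != len(y):
        raise ValueError("need n >= 3 paired observations")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValueError("x is constant: slope undefined")
    beta1 = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    beta0 = float(y.mean() - beta1 * x.mean())
    resid = y - (beta0 + beta1 * x)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return CorrectionModel(
        beta0=beta0, beta1=beta1, adjusted_r2=float(adj), n=n, target=target
    )


def kfold_cv_r2(x: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0) -> float:
    """Pooled out-of-fold R^2 of the linear correction.

    Rows are put in a canonical (x, y) sort order before the seeded
    shuffle, so the result depends only on the data and the seed, not on
    input row order.  Out-of-fold predictions are pooled and R^2 computed
    once on the pooled residuals.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n")
    order = np.lexsort((y, x))
    x, y = x[order], y[order]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    pred = np.empty(n)
    for fold in folds:
        train = np.setdiff1d(perm, fold)
        m = fit_linear_correction(x[train], y[train])
        pred[fold] = m.beta0 + m.beta1 * x[fold]
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 1.0
    return float(1.0 - np.sum((y - pred) ** 2) / ss_tot)


def predict_corrected(model: CorrectionModel, x: np.ndarray | float):
    """Apply the correction.

    Counts are rounded half-up to integers and never corrected below the
    visible count when the slope is >= 1 (a correction for hidden berries
    cannot remove visible ones).
    """
    if model is None or not np.isfinite(model.beta0 + model.beta1):
        raise ValueError("model is not fitted")
    xv = np.asarray(x, dtype=float)
    yv = model.beta0 + model.beta1 * xv
    if model.target == "count":
        yv = np.floor(yv + 0.5)
        if model.beta1 >= 1.0:
            yv = np.maximum(yv, np.ceil(xv))
        yv = yv.astype(int)
    return yv if np.ndim(x) else yv.item()


def angle_variation_stats(series_set: list[AngleSeries]) -> dict:
    """Population summaries of across-angle count variation.

    Returns per-cluster relative changes versus the first angle, the
    maximum absolute change, and mean absolute count differences between
    opposing (0/180, 90/270) and adjacent (0/90, 90/180, ...) angle
    pairs; a wing shows up as large adjacent differences but similar
    opposing views.
    """
    rel_changes: list[float] = []
    opposing: list[float] = []
    adjacent: list[float] = []
    for s in series_set:
        changes = s.relative_change()
        rel_changes.extend(v for a, v in changes.items() if a != min(changes))
        c = s.counts
        for a, b in ((0, 180), (90, 270)):
            if a in c and b in c:
                opposing.append(abs(c[a] - c[b]))
        for a, b in ((0, 90), (90, 180), (180, 270), (270, 0)):
            if a in c and b in c:
                adjacent.append(abs(c[a] - c[b]))
    rel = np.asarray(rel_changes, dtype=float)
    return {
        "relative_changes": rel,
        "max_abs_change": float(np.abs(rel).max()) if rel.size else 0.0,
        "mean_abs_change": float(np.abs(rel).mean()) if rel.size else 0.0,
        "mean_opposing_diff": float(np.mean(opposing)) if opposing else np.nan,
        "mean_adjacent_diff": float(np.mean(adjacent)) if adjacent else np.nan,
    }
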