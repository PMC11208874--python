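"""Mask-record I/O: COCO RLE codec, contour tracing, prompt grids.

Masks arrive as COCO run-length encodings in the *uncompressed* dialect:
runs are counted in column-major (Fortran) scan order and the first run
always counts background pixels, so an all-foreground mask starts with a
zero run.  The compressed LEB128-style string dialect is accepted on read
and canonicalized to the list form.

Coordinates are 0-based pixel indices with the origin at the top-left and
y increasing downward; the "top" of a cluster (the peduncle) is minimal y.
Contours are traced on pixel boundaries (crack edges), not through pixel
centers, so the shoelace area of a traced contour equals the pixel count
of a hole-free connected component exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.measure import label

__all__ = [
    "RLEMask",
    "MaskRecord",
    "PointGrid",
    "decode_rle",
    "encode_rle",
    "read_mask_records",
    "write_mask_records",
    "mask_to_contour",
    "generate_point_grid",
    "count_isolated_objects",
]


class MalformedRLEError(ValueError):
    """Run lengths are inconsistent with the declared mask size."""


class SchemaError(KeyError):
    """A required key is missing from a mask-record JSON object."""


@dataclass(frozen=True)
class RLEMask:
    """Uncompressed COCO RLE: ``size`` (height, width), alternating run
    lengths in column-major order starting with a background run."""

    size: tuple[int, int]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        h, w = self.size
        if any(c < 0 for c in self.counts):
            raise MalformedRLEError("negative run length")
        if sum(self.counts) != h * w:
            raise MalformedRLEError(
                f"run lengths sum to {sum(self.counts)}, expected {h * w}"
            )


@dataclass
class MaskRecord:
    """One raw segmented object as emitted by the mask generator."""

    mask: RLEMask
    bbox: tuple[int, int, int, int]  # x, y, w, h
    area: int
    predicted_iou: float
    stability_score: float
    mask_id: str = ""
    image_id: str | None = None
    cluster_id: str | None = None
    angle: int | None = None

    def decode(self) -> np.ndarray:
        return decode_rle(self.mask)


@dataclass(frozen=True)
class PointGrid:
    points: tuple[tuple[float, float], ...]
    n_per_side: int
    roi: tuple[float, float, float, float]


def decode_rle(rle: RLEMask) -> np.ndarray:
    """Decode an RLE mask to a boolean (height, width) grid."""
    h, w = rle.size
    values = np.arange(len(rle.counts)) % 2  # background first
    flat = np.repeat(values, rle.counts).astype(bool)
    return flat.reshape((h, w), order="F")


def encode_rle(grid: np.ndarray) -> RLEMask:
    """Encode a binary grid as uncompressed column-major COCO RLE."""
    arr = np.asarray(grid)
    if arr.dtype != bool:
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("encode_rle requires a binary grid")
        arr = arr.astype(bool)
    h, w = arr.shape
    flat = arr.flatten(order="F")
    if flat.size == 0:
        return RLEMask(size=(h, w), counts=(0,))
    change = np.flatnonzero(flat[1:] != flat[:-1]) + 1
    bounds = np.concatenate(([0], change, [flat.size]))
    counts = np.diff(bounds).tolist()
    if flat[0]:  # first run must count background
        counts = [0] + counts
    return RLEMask(size=(h, w), counts=tuple(int(c) for c in counts))


def _decode_compressed_counts(s: str) -> list[int]:
    """Decode the COCO compressed-string run-length dialect."""
    counts: list[int] = []
    i = 0
    while i < len(s):
        x, k, more = 0, 0, True
        while more:
            c = ord(s[i]) - 48
            x |= (c & 0x1F) << (5 * k)
            more = bool(c & 0x20)
            i += 1
            k += 1
        if x & (1 << (5 * k - 1)):  # sign-extend
            x -= 1 << (5 * k)
        if len(counts) > 2:
            x += counts[-2]
        counts.append(x)
    return counts


def _rle_from_segmentation(seg: dict) -> RLEMask:
    size = tuple(int(v) for v in seg["size"])
    counts = seg["counts"]
    if isinstance(counts, str):
        counts = _decode_compressed_counts(counts)
    return RLEMask(size=(size[0], size[1]), counts=tuple(int(c) for c in counts))


_REQUIRED_KEYS = ("segmentation", "bbox", "area", "predicted_iou", "stability_score")


def _tight_bbox(grid: np.ndarray) -> tuple[int, int, int, int]:
    ys, xs = np.nonzero(grid)
    x0, y0 = int(xs.min()), int(ys.min())
    return (x0, y0, int(xs.max()) - x0 + 1, int(ys.max()) - y0 + 1)


def read_mask_records(path: str | Path) -> list[MaskRecord]:
    """Read and validate mask records from a JSON file.

    Stored ``area`` and ``bbox`` inconsistent with the decoded mask are
    recomputed from the mask with a warning; a missing required key raises
    :class:`SchemaError` naming the key.
    """
    with open(path) as fh:
        raw = json.load(fh)
    records: list[MaskRecord] = []
    for i, obj in enumerate(raw):
        for key in _REQUIRED_KEYS:
            if key not in obj:
                raise SchemaError(f"record {i}: missing required key {key!r}")
        rle = _rle_from_segmentation(obj["segmentation"])
        grid = decode_rle(rle)
        n_fg = int(grid.sum())
        area = int(obj["area"])
        if area != n_fg:
            warnings.warn(
                f"record {i}: stored area {area} != decoded pixel count {n_fg}; "
                "recomputed from mask",
                stacklevel=2,
            )
            area = n_fg
        bbox = tuple(int(v) for v in obj["bbox"])
        if n_fg and bbox != _tight_bbox(grid):
            warnings.warn(
                f"record {i}: stored bbox is not the tight box of the mask; "
                "recomputed",
                stacklevel=2,
            )
            bbox = _tight_bbox(grid)
        records.append(
            MaskRecord(
                mask=rle,
                bbox=bbox,  # type: ignore[arg-type]
                area=area,
                predicted_iou=float(obj["predicted_iou"]),
                stability_score=float(obj["stability_score"]),
                mask_id=str(obj.get("mask_id", i)),
                image_id=obj.get("image_id"),
                cluster_id=obj.get("cluster_id"),
                angle=obj.get("angle"),
            )
        )
    return records


def write_mask_records(records: Sequence[MaskRecord], path: str | Path) -> None:
    """Serialize records to the mask-records JSON schema (canonical
    uncompressed RLE)."""
    out = []
    for r in records:
        out.append(
            {
                "segmentation": {"size": list(r.mask.size), "counts": list(r.mask.counts)},
                "bbox": list(r.bbox),
                "area": r.area,
                "predicted_iou": r.predicted_iou,
                "stability_score": r.stability_score,
                "mask_id": r.mask_id,
                "image_id": r.image_id,
                "cluster_id": r.cluster_id,
                "angle": r.angle,
            }
        )
    Path(path).write_text(json.dumps(out))


# crack-edge boundary tracing ------------------------------------------------

_DIRS = ((1, 0), (0, 1), (-1, 0), (0, -1))  # R, D, L, U


def _trace_crack_boundary(fg: np.ndarray) -> np.ndarray:
    """Walk the outer crack boundary of a 4-connected foreground region.

    The walk keeps foreground on its right; at ambiguous (pinch) vertices
    the right-most turn is taken, hugging the current pixel run so the
    enclosed shoelace area equals the region's pixel count.
    """
    h, w = fg.shape

    def pix(x: int, y: int) -> bool:
        return 0 <= x < w and 0 <= y < h and fg[y, x]

    def valid(x: int, y: int, d: int) -> bool:
        if d == 0:
            return pix(x, y) and not pix(x, y - 1)
        if d == 1:
            return pix(x - 1, y) and not pix(x, y)
        if d == 2:
            return pix(x - 1, y - 1) and not pix(x - 1, y)
        return pix(x, y - 1) and not pix(x - 1, y - 1)

    ys, xs = np.nonzero(fg)
    i = np.lexsort((xs, ys))[0]  # topmost, then leftmost pixel
    sx, sy = int(xs[i]), int(ys[i])
    verts: list[tuple[int, int]] = []
    x, y, d = sx, sy, 0
    while True:
        verts.append((x, y))
        x += _DIRS[d][0]
        y += _DIRS[d][1]
        if (x, y) == (sx, sy):
            break
        for nd in ((d + 1) % 4, d, (d - 1) % 4):
            if valid(x, y, nd):
                d = nd
                break
        else:  # pragma: no cover - unreachable on valid masks
            raise RuntimeError("boundary trace stuck")
    return np.asarray(verts, dtype=float)


def mask_to_contour(grid: np.ndarray) -> np.ndarray:
    """Trace the boundary of the largest connected component of ``grid``.

    Returns an (N, 2) array of (x, y) vertices on pixel boundaries,
    counter-clockwise in image coordinates (y down), first vertex not
    repeated.  Components other than the largest are dropped with a
    warning.
    """
    arr = np.asarray(grid).astype(bool)
    if not arr.any():
        raise ValueError("mask has no foreground pixels")
    labels = label(arr, connectivity=1)
    n_comp = labels.max()
    if n_comp > 1:
        sizes = np.bincount(labels.ravel())[1:]
        keep = int(np.argmax(sizes)) + 1
        warnings.warn(
            f"mask has {n_comp} components; keeping largest "
            f"({sizes[keep - 1]} px), dropping {sizes.sum() - sizes[keep - 1]} px",
            stacklevel=2,
        )
        arr = labels == keep
    verts = _trace_crack_boundary(arr)
    # trace keeps foreground on the right => clockwise in image coords;
    # reverse for counter-clockwise (y down) orientation
    return verts[::-1].copy()


def generate_point_grid(
    roi: tuple[float, float, float, float], n_per_side: int
) -> PointGrid:
    """Uniform n x n prompt grid at the cell centers of the ROI.

    Point spacing is (w/n, h/n); a 32 x 32 grid on a 2816 x 5472 ROI gives
    the 88 x 171 px spacing used with 20 Mpx captures.
    """
    if n_per_side < 1:
        raise ValueError("n_per_side must be >= 1")
    x0, y0, w, h = roi
    if w <= 0 or h <= 0:
        raise ValueError("roi must have positive width and height")
    sx, sy = w / n_per_side, h / n_per_side
    pts = tuple(
        (x0 + (i + 0.5) * sx, y0 + (j + 0.5) * sy)
        for j in range(n_per_side)
        for i in range(n_per_side)
    )
    return PointGrid(points=pts, n_per_side=n_per_side, roi=tuple(roi))


def count_isolated_objects(image: np.ndarray, min_area: int = 20) -> int:
    """Count dark, non-touching objects on a uniform bright surface.

    Global-threshold segmentation (Otsu) followed by connected-component
    labelling; components smaller than ``min_area`` pixels are discarded.
    Used to ground-truth berry counts from detached-berry validation
    images.
    """
    from skimage.filters import threshold_otsu

    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.max() == img.min():
        return 0
    fg = img < threshold_otsu(img)
    labels = label(fg, connectivity=1)
    if labels.max() == 0:
        return 0
    sizes = np.bincount(labels.ravel())[1:]
    return int((sizes >= min_area).sum())
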