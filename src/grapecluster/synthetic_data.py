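"""Ground-truthed synthetic grape clusters for pipeline testing.

Berries are spheres packed around a vertical rachis axis (taper narrows
the cluster toward the tip); an optional wing is a smaller sub-cluster
offset laterally at a given azimuth, so it is visible from the view
angles where that azimuth projects onto the image plane and hides behind
the main cluster a quarter turn later.  Views are orthographic
projections with a per-pixel z-buffer: the nearest sphere owns each
pixel, so visible berry masks are pairwise disjoint and partially hidden
berries render as crescents, exactly like real occlusion.  Roughly half
the berries of a default cluster are hidden from any one view, matching
what hanging-cluster photographs show.

Distractor objects (clamp, size-reference circle, rachis segments,
background stains) and merged multi-berry masks can be injected with
full ground-truth labels, and a whole scene exports to the same
mask-records JSON schema the segmentation engine emits, so the generator
doubles as a segmenter-adapter stub.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mask_io import MaskRecord, encode_rle

__all__ = [
    "WingSpec",
    "ClusterSpec",
    "Cluster3D",
    "RenderedScene",
    "ArtifactConfig",
    "simulate_cluster_3d",
    "render_view",
    "inject_artifacts",
    "scene_to_mask_records",
    "simulate_trial",
]

# Radial cluster extent per berry radius: R0 = _RADIAL_FACTOR * r *
# sqrt(berries per internode).  With the default berries-per-node the
# cross-section is ~2 berries deep, which hides about half the berries
# from any single view; because rachis length scales with berry count by
# default, the hidden fraction is size-independent and the visible-count
# underestimation stays linear.
_RADIAL_FACTOR = 0.94
_BERRIES_PER_NODE = 5.5


@dataclass(frozen=True)
class WingSpec:
    """A lateral ramification.  ``azimuth_deg`` = 90 puts the wing on the
    +x side of the 0-degree view (hidden along the depth axis at 90/270)."""

    azimuth_deg: float = 90.0
    length_fraction: float = 0.45  # of rachis length
    berry_share: float = 0.3


@dataclass(frozen=True)
class ClusterSpec:
    n_berries: int = 45
    berry_radius_mean: float = 14.0  # px
    berry_radius_sd: float = 1.2
    rachis_length: float | None = None  # px; None = scale with berry count
    internode_spacing: float = 16.0  # px
    taper: float = 0.35  # conical narrowing toward the tip
    wing: WingSpec | None = None
    packing_density: float = 0.65  # min separation x (r_i + r_j)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_berries < 1:
            raise ValueError("n_berries must be >= 1")
        if self.berry_radius_mean <= 0:
            raise ValueError("berry radius must be positive")
        if self.rachis_length is not None and self.rachis_length <= 0:
            raise ValueError("rachis length must be positive")
        if self.wing is not None and not 0 <= self.wing.berry_share < 1:
            raise ValueError("wing berry share must be in [0, 1)")


@dataclass
class Cluster3D:
    """Berry centers/radii in 3D: x lateral, y vertical (0 = peduncle,
    increasing toward the tip), z depth.

    ``aspect``/``tilt`` describe each berry's slightly elliptical outline
    (real berries are not perfect circles); they are per-berry constants
    so the same berry keeps its shape across view angles.
    """

    centers: np.ndarray  # (n, 3)
    radii: np.ndarray  # (n,)
    is_wing: np.ndarray  # (n,) bool
    aspect: np.ndarray  # (n,) outline minor/major in (0, 1]
    tilt: np.ndarray  # (n,) outline major-axis tilt from vertical, rad
    spec: ClusterSpec


@dataclass
class RenderedScene:
    angle: float
    image_size: tuple[int, int]  # (height, width)
    scale_mm_per_px: float
    owner: np.ndarray  # (H, W) int, -1 = background
    centers_px: np.ndarray  # (n, 2) projected berry centers (x, y)
    radii: np.ndarray
    visible_areas: np.ndarray  # pixels owned per berry
    true_count: int
    true_areas_mm2: np.ndarray  # full-disk pi r^2, mm^2
    min_visible_fraction: float = 0.2
    outline_aspect: np.ndarray | None = None  # per-berry outline minor/major
    outline_tilt: np.ndarray | None = None  # per-berry tilt from vertical, rad
    distractors: list[tuple[str, np.ndarray]] = field(default_factory=list)
    merged_masks: list[tuple[np.ndarray, list[int]]] = field(default_factory=list)

    @property
    def detected_ids(self) -> np.ndarray:
        """Berries whose visible area reaches the detectability floor."""
        frac = self.visible_areas / (np.pi * self.radii**2)
        return np.flatnonzero(frac >= self.min_visible_fraction)

    @property
    def visible_count(self) -> int:
        return int(len(self.detected_ids))

    def berry_mask(self, i: int) -> np.ndarray:
        """Visible (owned) pixels of berry ``i``; crescents when occluded."""
        return self.owner == i

    def berry_full_mask(self, i: int) -> np.ndarray:
        """Complete projected outline of berry ``i``, ignoring occluders.

        This is what a boundary-completing segmenter reports for a
        detected berry: a slightly elliptical disk of the berry's full
        projected size.
        """
        h, w = self.image_size
        cx, cy = self.centers_px[i]
        r = self.radii[i]
        asp = 1.0 if self.outline_aspect is None else self.outline_aspect[i]
        tilt = 0.0 if self.outline_tilt is None else self.outline_tilt[i]
        a, b = r / np.sqrt(asp), r * np.sqrt(asp)  # vertical-ish major axis
        yy, xx = np.mgrid[0:h, 0:w]
        dx, dy = xx + 0.5 - cx, yy + 0.5 - cy
        u = dx * np.sin(tilt) + dy * np.cos(tilt)  # along major axis
        v = dx * np.cos(tilt) - dy * np.sin(tilt)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def to_image(self) -> np.ndarray:
        """Flat-fill RGB rendering (background, berries, distractors)."""
        h, w = self.image_size
        img = np.full((h, w, 3), 235, dtype=np.uint8)
        img[self.owner >= 0] = (88, 44, 104)  # berry purple
        for kind, mask in self.distractors:
            color = {
                "clamp": (60, 60, 60),
                "reference_circle": (20, 20, 20),
                "rachis": (96, 120, 60),
                "stain": (180, 170, 150),
            }.get(kind, (128, 128, 128))
            img[mask] = color
        return img


@dataclass(frozen=True)
class ArtifactConfig:
    clamp: bool = True
    reference_circle_diameter_px: float | None = 140.0
    reference_diameter_mm: float = 35.0
    n_rachis: int = 2
    n_stains: int = 2
    n_merged: int = 3


def _taper_radius(taper: float, y: np.ndarray, L: float, base: float) -> np.ndarray:
    return base * (1.0 - taper * y / L)

def simulate_cluster_3d(spec: ClusterSpec) -> Cluster3D:
    """Place berry spheres around the rachis axis, deterministically.

    Main berries sit at jittered internode heights with radial distance
    bounded by the tapered cluster radius; wing berries form a smaller
    laterally offset sub-cluster.  Pairwise overlap is relaxed until all
    center distances reach ``packing_density * (r_i + r_j)``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_berries
    radii = np.clip(
        rng.normal(spec.berry_radius_mean, spec.berry_radius_sd, n),
        0.5 * spec.berry_radius_mean,
        1.5 * spec.berry_radius_mean,
    )
    n_wing = int(round(spec.wing.berry_share * n)) if spec.wing else 0
    n_main = n - n_wing
    L = spec.rachis_length
    if L is None:
        L = spec.internode_spacing * max(n_main, 6) / _BERRIES_PER_NODE
    per_node = n_main / max(L / spec.internode_spacing, 1.0)
    base_r = _RADIAL_FACTOR * spec.berry_radius_mean * np.sqrt(max(per_node, 1.0))

    # main berries: uniform along internode heights, radial jitter in the
    # tapered envelope
    n_nodes = max(2, int(L / spec.internode_spacing))
    y = (rng.integers(0, n_nodes, n_main) + rng.uniform(-0.4, 0.4, n_main)) * (
        L / n_nodes
    )
    y = np.clip(y, 0, L)
    env = np.maximum(_taper_radius(spec.taper, y, L, base_r), 0.3 * base_r)
    rho = env * np.sqrt(rng.uniform(0, 1, n_main))
    phi = rng.uniform(0, 2 * np.pi, n_main)
    main = np.column_stack([rho * np.cos(phi), y, rho * np.sin(phi)])

    if n_wing:
        az = np.deg2rad(spec.wing.azimuth_deg)
        u = np.array([np.sin(az), 0.0, np.cos(az)])  # lateral offset dir
        wing_r = max(
            0.9 * spec.berry_radius_mean,
            _RADIAL_FACTOR * spec.berry_radius_mean * max(n_wing, 1) ** (1.0 / 3.0),
        )
        offset = (base_r + wing_r + 0.6 * spec.berry_radius_mean) * u
        wy0 = 0.1 * L
        wy = wy0 + rng.uniform(0, spec.wing.length_fraction * L, n_wing)
        wrho = wing_r * np.sqrt(rng.uniform(0, 1, n_wing))
        wphi = rng.uniform(0, 2 * np.pi, n_wing)
        wing = (
            np.column_stack([wrho * np.cos(wphi), wy, wrho * np.sin(wphi)])
            + offset
        )
        centers = np.vstack([main, wing])
    else:
        centers = main
    is_wing = np.zeros(n, dtype=bool)
    is_wing[n_main:] = True

    # pairwise separation relaxation
    min_sep = spec.packing_density * np.add.outer(radii, radii)
    np.fill_diagonal(min_sep, 0.0)
    for _ in range(300):
        diff = centers[:, None, :] - centers[None, :, :]
        dist = np.linalg.norm(diff, axis=2)
        np.fill_diagonal(dist, np.inf)
        deficit = min_sep - dist
        bad = deficit > 1e-6
        if not bad.any():
            break
        push = np.zeros_like(centers)
        ii, jj = np.nonzero(bad)
        for a, b in zip(ii, jj):
            if dist[a, b] < 1e-9:
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
            else:
                d = diff[a, b] / dist[a, b]
            push[a] += 0.5 * deficit[a, b] * d
        centers = centers + 0.6 * push
    else:
        raise RuntimeError(
            "infeasible packing: relaxation did not converge; "
            "lower packing_density or n_berries"
        )
    aspect = rng.uniform(0.86, 1.0, n)
    tilt = rng.uniform(-0.35, 0.35, n)
    return Cluster3D(
        centers=centers,
        radii=radii,
        is_wing=is_wing,
        aspect=aspect,
        tilt=tilt,
        spec=spec,
    )


def render_view(
    cluster: Cluster3D,
    angle: float = 0.0,
    image_size: tuple[int, int] | None = None,
    scale_mm_per_px: float = 0.47,
    min_visible_fraction: float = 0.2,
) -> RenderedScene:
    """Orthographic z-buffer rendering of one view angle.

    The cluster is rotated about the vertical axis, projected, and each
    pixel inside at least one sphere is assigned to the nearest sphere.
    Berries with no owned pixels are fully hidden.
    """
    th = np.deg2rad(angle)
    x = cluster.centers[:, 0] * np.cos(th) + cluster.centers[:, 2] * np.sin(th)
    z = -cluster.centers[:, 0] * np.sin(th) + cluster.centers[:, 2] * np.cos(th)
    y = cluster.centers[:, 1]
    r = cluster.radii

    margin = 6.0 * cluster.spec.berry_radius_mean
    if image_size is None:
        w = int(np.ceil((x + r).max() - (x - r).min() + 2 * margin))
        h = int(np.ceil((y + r).max() - (y - r).min() + 2 * margin))
        image_size = (h, w)
    h, w = image_size
    px = x - (x - r).min() + (w - ((x + r).max() - (x - r).min())) / 2.0
    py = y - (y - r).min() + (h - ((y + r).max() - (y - r).min())) / 2.0
    if (px - r).min() < 0 or (px + r).max() > w or (py - r).min() < 0 or (
        py + r
    ).max() > h:
        raise ValueError("berries do not fit in the requested frame")

    depth = np.full((h, w), np.inf)
    owner = np.full((h, w), -1, dtype=np.int32)
    for i in range(len(r)):
        x0, x1 = int(np.floor(px[i] - r[i])), int(np.ceil(px[i] + r[i])) + 1
        y0, y1 = int(np.floor(py[i] - r[i])), int(np.ceil(py[i] + r[i])) + 1
        yy, xx = np.mgrid[y0:y1, x0:x1]
        rho2 = (xx + 0.5 - px[i]) ** 2 + (yy + 0.5 - py[i]) ** 2
        inside = rho2 <= r[i] ** 2
        d = np.where(inside, z[i] - np.sqrt(np.maximum(r[i] ** 2 - rho2, 0.0)), np.inf)
        patch = depth[y0:y1, x0:x1]
        closer = d < patch
        patch[closer] = d[closer]
        owner[y0:y1, x0:x1][closer] = i
    visible = np.bincount(owner[owner >= 0].ravel(), minlength=len(r)).astype(float)
    return RenderedScene(
        angle=angle,
        image_size=(h, w),
        scale_mm_per_px=scale_mm_per_px,
        owner=owner,
        centers_px=np.column_stack([px, py]),
        radii=r.copy(),
        visible_areas=visible,
        true_count=len(r),
        true_areas_mm2=np.pi * (r * scale_mm_per_px) ** 2,
        min_visible_fraction=min_visible_fraction,
        outline_aspect=cluster.aspect.copy(),
        outline_tilt=cluster.tilt.copy(),
    )


def _disk_mask(h: int, w: int, cx: float, cy: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= radius**2


def _rot_rect_mask(
    h: int, w: int, cx: float, cy: float, length: float, width: float, theta: float
) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx + 0.5 - cx, yy + 0.5 - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (np.abs(u) <= length / 2) & (np.abs(v) <= width / 2)


def inject_artifacts(
    scene: RenderedScene,
    config: ArtifactConfig = ArtifactConfig(),
    seed: int = 0,
) -> RenderedScene:
    """Add labelled distractor objects and merged masks to a scene.

    The clamp sits just above the topmost berry (the peduncle end); the
    reference circle and stains are placed in free background away from
    the cluster; rachis segments are thin elongated rectangles near the
    cluster top; merged masks are unions of the visible masks of touching
    detected berry pairs/triples.
    """
    rng = np.random.default_rng(seed)
    out = replace(scene)

    # widen the frame with a free band on the right for the reference
    # circle, so it never overlaps the cluster
    if config.reference_circle_diameter_px:
        pad = int(config.reference_circle_diameter_px) + 16
        out.owner = np.pad(scene.owner, ((0, 0), (0, pad)), constant_values=-1)
        out.image_size = (scene.image_size[0], scene.image_size[1] + pad)
    h, w = out.image_size
    r_mean = float(out.radii.mean())
    cx, cy = out.centers_px.mean(axis=0)
    distractors: list[tuple[str, np.ndarray]] = []

    if config.clamp:
        top = out.centers_px[:, 1].min() - out.radii.max()
        mask = _rot_rect_mask(
            h, w, cx + rng.uniform(-5, 5), max(top - 1.6 * r_mean, 1.2 * r_mean),
            1.2 * r_mean, 3.2 * r_mean, np.pi / 2,
        )
        distractors.append(("clamp", mask))

    if config.reference_circle_diameter_px:
        rad = config.reference_circle_diameter_px / 2.0
        mask = _disk_mask(h, w, w - rad - 8, rng.uniform(rad + 8, h - rad - 8), rad)
        distractors.append(("reference_circle", mask))

    for _ in range(config.n_rachis):
        ang = rng.uniform(0, np.pi)
        rx = cx + rng.uniform(-2, 2) * r_mean
        ry = out.centers_px[:, 1].min() + rng.uniform(0, 4) * r_mean
        mask = _rot_rect_mask(h, w, rx, ry, 7.0 * r_mean, 0.55 * r_mean, ang)
        distractors.append(("rachis", mask))

    for _ in range(config.n_stains):
        # background stains in the left margin, far from the cluster
        sx = rng.uniform(1.6 * r_mean, 2.6 * r_mean)
        sy = rng.uniform(0.1, 0.9) * h
        base = _disk_mask(h, w, sx, sy, rng.uniform(0.9, 1.4) * r_mean)
        blob = base | _disk_mask(
            h, w, sx + rng.uniform(-1, 1) * r_mean, sy + rng.uniform(-1, 1) * r_mean,
            rng.uniform(0.6, 1.0) * r_mean,
        )
        distractors.append(("stain", blob))

    merged: list[tuple[np.ndarray, list[int]]] = []
    det = out.detected_ids
    if config.n_merged and len(det) >= 2:
        # touching detected pairs: center distance below the radius sum
        pairs = [
            (i, j)
            for ai, i in enumerate(det)
            for j in det[ai + 1 :]
            if np.linalg.norm(out.centers_px[i] - out.centers_px[j])
            < 1.05 * (out.radii[i] + out.radii[j])
        ]
        rng.shuffle(pairs)
        for i, j in pairs[: config.n_merged]:
            members = [int(i), int(j)]
            mask = out.berry_full_mask(int(i)) | out.berry_full_mask(int(j))
            merged.append((mask, members))

    out.distractors = scene.distractors + distractors
    out.merged_masks = scene.merged_masks + merged
    return out


def scene_to_mask_records(
    scene: RenderedScene, seed: int = 0
) -> tuple[list[MaskRecord], dict[str, str]]:
    """Export a scene in the mask-records schema with ground-truth labels.

    Returns (records, truth) where truth maps mask_id to one of
    ``berry``, ``merged``, ``clamp``, ``reference_circle``, ``rachis``,
    ``stain``.  Only berries at or above the detectability floor are
    emitted, mimicking the mask generator's stability filtering, and a
    detected berry's record carries its complete projected outline (the
    boundary-completed mask a segmenter reports), not the occluded
    crescent.
    """
    rng = np.random.default_rng(seed)
    records: list[MaskRecord] = []
    truth: dict[str, str] = {}

    def add(mask: np.ndarray, mask_id: str, kind: str) -> None:
        ys, xs = np.nonzero(mask)
        if len(xs) == 0:
            return
        bbox = (
            int(xs.min()),
            int(ys.min()),
            int(xs.max() - xs.min() + 1),
            int(ys.max() - ys.min() + 1),
        )
        records.append(
            MaskRecord(
                mask=encode_rle(mask),
                bbox=bbox,
                area=int(mask.sum()),
                predicted_iou=float(rng.uniform(0.85, 1.0)),
                stability_score=float(rng.uniform(0.9, 1.0)),
                mask_id=mask_id,
                angle=int(scene.angle) if scene.angle in (0, 90, 180, 270) else None,
            )
        )
        truth[mask_id] = kind

    for i in scene.detected_ids:
        add(scene.berry_full_mask(int(i)), f"b{i}", "berry")
    for k, (mask, members) in enumerate(scene.merged_masks):
        add(mask, f"m{k}", "merged")
    for k, (kind, mask) in enumerate(scene.distractors):
        add(mask, f"d{k}_{kind}", kind)
    return records, truth


def simulate_trial(
    n_genotypes: int = 100,
    n_blocks: int = 3,
    clusters_per_vine: int = 5,
    trait_model: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a randomized-complete-block trait table.

    value = mu + g_i + b_j + e_ij + w_ijc with independent zero-mean
    normal effects: genotype g, block b, vine-level residual e and
    cluster-level subsampling noise w (variance key ``sigma2_cluster``,
    default 0).  Cluster replicates average to the vine, so the vine-level
    phenotypic variance is sigma2_g + sigma2_e + sigma2_cluster/c; the
    exact repeatability at that level is recorded in
    ``df.attrs['true_repeatability']``.
    """
    tm = {
        "mu": 50.0,
        "sigma2_g": 6.0,
        "sigma2_block": 2.0,
        "sigma2_e": 4.0,
        "sigma2_cluster": 0.0,
    }
    if trait_model:
        tm.update(trait_model)
    if min(tm["sigma2_g"], tm["sigma2_block"], tm["sigma2_e"], tm["sigma2_cluster"]) < 0:
        raise ValueError("variances must be >= 0")
    rng = np.random.default_rng(seed)
    g = rng.normal(0, np.sqrt(tm["sigma2_g"]), n_genotypes)
    b = rng.normal(0, np.sqrt(tm["sigma2_block"]), n_blocks)
    e = rng.normal(0, np.sqrt(tm["sigma2_e"]), (n_genotypes, n_blocks))
    rows = []
    for i in range(n_genotypes):
        for j in range(n_blocks):
            for c in range(clusters_per_vine):
                rows.append(
                    {
                        "genotype": f"G{i:03d}",
                        "block": f"B{j}",
                        "vine": f"G{i:03d}-B{j}",
                        "cluster": c,
                        "value": tm["mu"]
                        + g[i]
                        + b[j]
                        + e[i, j]
                        + rng.normal(0, np.sqrt(tm["sigma2_cluster"])),
                    }
                )
    df = pd.DataFrame(rows)
    resid = tm["sigma2_e"] + tm["sigma2_cluster"] / clusters_per_vine
    denom = tm["sigma2_g"] + resid
    df.attrs["true_repeatability"] = 0.0 if denom == 0 else tm["sigma2_g"] / denom
    return df
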