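"""Shared geometry helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import binary_fill_holes


def circle_contour(r: float = 10.0, n: int = 360, center=(0.0, 0.0)) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])


def ellipse_contour(a: float, b: float, n: int = 360, rot: float = 0.0) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([a * np.cos(th), b * np.sin(th)])
    R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
    return pts @ R.T


def disk_mask(shape=(60, 60), center=(30, 30), r: float = 20.0) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= r * r


def random_blob_mask(seed: int, shape=(48, 48)) -> np.ndarray:
    """Hole-free random blob: union of drifting disks, gaps flooded away."""
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    g = np.zeros(shape, bool)
    cx, cy = shape[1] / 2, shape[0] / 2
    for _ in range(int(rng.integers(2, 6))):
        cx += rng.uniform(-6, 6)
        cy += rng.uniform(-6, 6)
        r = rng.uniform(3, 8)
        g |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    return binary_fill_holes(g, structure=np.ones((3, 3)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
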