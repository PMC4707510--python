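"""Shared fixtures and oracles for the test suite.

All fixtures are generated programmatically; the brute-force oracles here
are deliberately naive (all-pairs scans, per-voxel loops) and independent
of the library code paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from spheromorph.images import BinaryMask
from spheromorph.revolution import align_to_feret


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else 1.0


def digital_disk(radius_px: float, side: int | None = None, pixel_size: float = 1.0) -> BinaryMask:
    side = side or (2 * int(math.ceil(radius_px)) + 21)
    c = (side - 1) / 2.0
    yy, xx = np.mgrid[:side, :side]
    return BinaryMask((yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2, pixel_size)


def digital_ellipse(
    a_px: float, b_px: float, angle: float = 0.0, side: int | None = None, pixel_size: float = 1.0
) -> BinaryMask:
    side = side or (2 * int(math.ceil(a_px)) + 21)
    c = (side - 1) / 2.0
    yy, xx = np.mgrid[:side, :side]
    x = xx - c
    y = yy - c
    ca, sa = math.cos(angle), math.sin(angle)
    u = (x * ca + y * sa) / a_px
    v = (-x * sa + y * ca) / b_px
    return BinaryMask(u * u + v * v <= 1.0, pixel_size)


def random_blob(rng: np.random.Generator, side: int = 96, n_disks: int = 4) -> BinaryMask:
    """Union of overlapping random disks: a single-part, convex-ish blob."""
    yy, xx = np.mgrid[:side, :side]
    m = np.zeros((side, side), bool)
    cy, cx = rng.uniform(side * 0.38, side * 0.62, 2)
    for _ in range(n_disks):
        r = rng.uniform(side * 0.1, side * 0.2)
        dy, dx = rng.uniform(-side * 0.1, side * 0.1, 2)
        m |= (yy - cy - dy) ** 2 + (xx - cx - dx) ** 2 <= r * r
    return BinaryMask(m, 1.0)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_feret(mask_px: np.ndarray) -> tuple[float, float]:
    """Exhaustive all-pairs maximum distance over foreground pixel centers.

    Returns (length, angle); ties broken toward the smaller angle in [0, π).
    """
    pts = np.argwhere(mask_px)
    best = -1.0
    best_angle = 0.0
    for i in range(len(pts)):
        d = pts[i + 1 :] - pts[i]
        if len(d) == 0:
            continue
        dist = np.hypot(d[:, 0], d[:, 1])
        for j in np.nonzero(dist >= dist.max() - 1e-12)[0]:
            L = float(dist[j])
            dr, dc = float(d[j, 0]), float(d[j, 1])
            if dc < 0 or (dc == 0 and dr < 0):
                dr, dc = -dr, -dc
            ang = math.atan2(dr, dc) % math.pi
            if L > best + 1e-9 or (abs(L - best) <= 1e-9 and ang < best_angle - 1e-12):
                best, best_angle = L, ang
    return best, best_angle


def brute_force_revolved_count(mask_px: np.ndarray) -> int:
    """Naive solid-of-revolution voxel count for a single-part mask.

    Mirrors the estimator's contract with explicit loops: align the feret
    axis (found by all-pairs scan) to the columns, then for every column
    run sweep a disk and test every (y, z) voxel against the circle
    equation, counting each occupied voxel once per column plane.
    """
    _, angle = brute_force_feret(mask_px)
    arr = align_to_feret(mask_px, angle, reshape=True)
    h, w = arr.shape
    total = 0
    for c in range(w):
        col = arr[:, c]
        runs = []
        r = 0
        while r < h:
            if not col[r]:
                r += 1
                continue
            r0 = r
            while r < h and col[r]:
                r += 1
            runs.append((r0, r - 1))
        if not runs:
            continue
        zmax = max(int(math.ceil((b - a + 1) / 2.0)) for a, b in runs)
        occupied = set()
        for r0, r1 in runs:
            yc = (r0 + r1) / 2.0
            radius = (r1 - r0 + 1) / 2.0
            for y in range(h):
                for z in range(-zmax, zmax + 1):
                    if (y - yc) ** 2 + z * z <= radius * radius:
                        occupied.add((y, z))
        total += len(occupied)
    return total


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
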