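"""Geometry kernels: Shrake–Rupley SASA, grid van-der-Waals volume, and
Monte-Carlo projection-approximation collision cross-section (CCS).

All three operate on bare ``(coords, radii)`` arrays so they can run per
trajectory frame without touching topology. SASA uses a deterministic
Fibonacci sphere-point lattice; the CCS estimator averages rasterized
projected union areas over seeded uniformly random orientations, so its
only stochastic element is the orientation draw. A fine-grid deterministic
CCS oracle is provided for cross-validation on small systems.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import DataError

log = logging.getLogger(__name__)


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors on the sphere (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def shrake_rupley_sasa(coords: np.ndarray, radii: np.ndarray,
                       probe: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²).

    Each atom's accessible area is ``4π(r+probe)²`` times the fraction of
    quasi-uniform test points on its expanded sphere that fall inside no
    other atom's expanded sphere. Deterministic for a fixed point count.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a usable point lattice")
    if np.any(radii <= 0):
        raise ValueError("all radii must be positive")
    n = len(coords)
    expanded = radii + probe
    unit = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    # coincident atoms are legal but may shadow each other completely
    close = tree.query_pairs(r=1e-9)
    if close:
        log.warning("%d coincident atom pair(s); both treated normally", len(close))
    areas = np.empty(n)
    rmax = expanded.max()
    for i in range(n):
        ri = expanded[i]
        neighbors = [j for j in tree.query_ball_point(coords[i], ri + rmax)
                     if j != i and np.dot(coords[i] - coords[j], coords[i] - coords[j])
                     < (ri + expanded[j]) ** 2]
        pts = coords[i] + ri * unit
        if neighbors:
            d2 = ((pts[:, None, :] - coords[neighbors][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[neighbors] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * ri * ri * frac
    return areas


def molecular_volume(coords: np.ndarray, radii: np.ndarray,
                     voxel: float = 0.3) -> float:
    """Van-der-Waals volume (Å³) by voxel counting.

    Counts grid centers lying inside at least one atom sphere over a
    bounding box padded by the largest radius.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if voxel <= 0:
        raise ValueError("voxel must be positive")
    pad = radii.max() + voxel
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    dims = np.ceil((hi - lo) / voxel).astype(int) + 1
    occupied = np.zeros(dims, dtype=bool)
    axes = [lo[k] + voxel * np.arange(dims[k]) for k in range(3)]
    for c, r in zip(coords, radii):
        i0 = np.maximum(((c - r - lo) / voxel).astype(int), 0)
        i1 = np.minimum(((c + r - lo) / voxel).astype(int) + 2, dims)
        gx = axes[0][i0[0]:i1[0]] - c[0]
        gy = axes[1][i0[1]:i1[1]] - c[1]
        gz = axes[2][i0[2]:i1[2]] - c[2]
        d2 = (gx[:, None, None] ** 2 + gy[None, :, None] ** 2
              + gz[None, None, :] ** 2)
        occupied[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= d2 <= r * r
    return float(occupied.sum()) * voxel ** 3


@dataclass
class CcsResult:
    """Projection-approximation CCS with Monte-Carlo uncertainty."""

    ccs: float                 # Å²
    mc_standard_error: float   # Å², over orientations
    n_orientations: int
    probe_radius: float
    seed: int


def _projected_union_area(xy: np.ndarray, rr: np.ndarray, pixel: float) -> float:
    """Union area of discs (centers ``xy``, radii ``rr``) by rasterization."""
    lo = (xy - rr[:, None]).min(axis=0) - pixel
    hi = (xy + rr[:, None]).max(axis=0) + pixel
    nx, ny = (np.ceil((hi - lo) / pixel).astype(int) + 1)
    grid = np.zeros((nx, ny), dtype=bool)
    xs = lo[0] + pixel * np.arange(nx)
    ys = lo[1] + pixel * np.arange(ny)
    for (cx, cy), r in zip(xy, rr):
        i0 = max(int((cx - r - lo[0]) / pixel), 0)
        i1 = min(int((cx + r - lo[0]) / pixel) + 2, nx)
        j0 = max(int((cy - r - lo[1]) / pixel), 0)
        j1 = min(int((cy + r - lo[1]) / pixel) + 2, ny)
        d2 = ((xs[i0:i1, None] - cx) ** 2 + (ys[None, j0:j1] - cy) ** 2)
        grid[i0:i1, j0:j1] |= d2 <= r * r
    return float(grid.sum()) * pixel * pixel


def ccs_projection_approximation(coords: np.ndarray, radii: np.ndarray,
                                 probe: float = 1.0,
                                 n_orientations: int = 32,
                                 seed: int = 0,
                                 pixel: float = 0.5) -> CcsResult:
    """Projection-approximation CCS: mean projected union area of
    probe-expanded spheres over seeded uniformly random orientations.

    Per-orientation areas come from deterministic rasterization at
    ``pixel`` resolution, so randomness enters only through orientations;
    the reported standard error is the orientation-to-orientation s.e.m.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if n_orientations < 1:
        raise ValueError("n_orientations must be >= 1")
    rng = np.random.default_rng(seed)
    rots = Rotation.random(n_orientations, rng=rng)
    center = coords.mean(axis=0)
    centered = coords - center
    rr = radii + probe
    areas = np.empty(n_orientations)
    for k, rot in enumerate(rots):
        xy = rot.apply(centered)[:, :2]
        areas[k] = _projected_union_area(xy, rr, pixel)
    se = float(areas.std(ddof=1) / np.sqrt(n_orientations)) if n_orientations > 1 else 0.0
    return CcsResult(ccs=float(areas.mean()), mc_standard_error=se,
                     n_orientations=n_orientations, probe_radius=probe, seed=seed)


def _basis_for_direction(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(v[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(v, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v, e1)
    return e1, e2


def ccs_grid_oracle(coords: np.ndarray, radii: np.ndarray,
                    probe: float = 1.0, grid: float = 0.1,
                    n_orientations: int = 128) -> float:
    """Deterministic fine-grid CCS oracle for small systems (≤100 atoms).

    Averages rasterized projected areas over a fixed Fibonacci-lattice set
    of viewing directions. Intended as a validation cross-check, not a
    production estimator.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    if coords.size == 0 or radii.size == 0:
        raise DataError("ccs_grid_oracle: zero atoms")
    if len(coords) > 100:
        raise DataError("ccs_grid_oracle is restricted to <=100 atoms")
    rr = radii + probe
    if grid > rr.min() / 2:
        raise DataError(f"grid {grid} Å too coarse for smallest expanded radius {rr.min():.2f} Å")
    center = coords.mean(axis=0)
    centered = coords - center
    areas = []
    for v in fibonacci_sphere(n_orientations):
        e1, e2 = _basis_for_direction(v)
        xy = centered @ np.column_stack([e1, e2])
        areas.append(_projected_union_area(xy, rr, grid))
    return float(np.mean(areas))
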