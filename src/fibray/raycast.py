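"""Fiber orientation estimation by ray-sum maximization.

At a query voxel, bidirectional rays are cast in every direction of a discrete
angular grid; the ray accumulating the largest sum of voxel intensities along
its path marks the local fiber axis.  Angles follow the convention: elevation
is the inclination from the Z axis in [0°, 90°], azimuth the in-plane (XY)
angle in [-90°, 90°); a fiber along Z has both components 0°.

The scan kernel is JIT-compiled with numba; a naive pure-Python reference with
identical nearest-voxel arithmetic lives in ``ray_sum_reference`` /
``estimate_orientation_reference`` and backs the equivalence tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit, prange

from .io import OrientationField, Volume, log_stage, logger


# ---------------------------------------------------------------------------
# Angles and grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Orientation:
    """(azimuth, elevation) angle pair in degrees."""

    azimuth: float
    elevation: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.azimuth < 90.0:
            raise ValueError(f"azimuth must lie in [-90, 90), got {self.azimuth}")
        if not 0.0 <= self.elevation <= 90.0:
            raise ValueError(f"elevation must lie in [0, 90], got {self.elevation}")

    def as_tuple(self) -> tuple[float, float]:
        return (self.azimuth, self.elevation)


def direction_vector(o: Orientation) -> np.ndarray:
    """Unit direction (x, y, z) of an orientation.

    ``(sin e cos a, sin e sin a, cos e)`` with ``e`` the elevation measured
    from Z and ``a`` the azimuth in the XY plane; (0°, 0°) maps to (0, 0, 1).
    """
    a = math.radians(o.azimuth)
    e = math.radians(o.elevation)
    v = np.array([math.sin(e) * math.cos(a), math.sin(e) * math.sin(a), math.cos(e)])
    return v


def orientation_from_vector(v: np.ndarray) -> Orientation:
    """Inverse of :func:`direction_vector` for an undirected axis.

    The vector is canonicalized to the upper hemisphere (z >= 0); the azimuth
    is folded into [-90, 90) by +-180 (period-180 reporting convention), and
    a Z-aligned axis reports azimuth 0.
    """
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector has no orientation")
    v = v / n
    if v[2] < 0:
        v = -v
    elevation = math.degrees(math.acos(min(1.0, max(-1.0, v[2]))))
    if elevation == 0.0:
        return Orientation(0.0, 0.0)
    azimuth = math.degrees(math.atan2(v[1], v[0]))
    if azimuth >= 90.0:
        azimuth -= 180.0
    elif azimuth < -90.0:
        azimuth += 180.0
    return Orientation(azimuth, min(elevation, 90.0))


@dataclass(frozen=True)
class AngularGrid:
    """Discrete scan ranges for azimuth and elevation (degrees; stop exclusive).

    Defaults cover azimuth -90..89 in 1° steps (180 values) and elevation
    0..89 in 1° steps (90 values).
    """

    azimuth_start: float = -90.0
    azimuth_stop: float = 90.0
    azimuth_step: float = 1.0
    elevation_start: float = 0.0
    elevation_stop: float = 90.0
    elevation_step: float = 1.0

    def __post_init__(self) -> None:
        if self.azimuth_step <= 0 or self.elevation_step <= 0:
            raise ValueError("angular steps must be > 0")

    def azimuths(self) -> np.ndarray:
        return np.arange(self.azimuth_start, self.azimuth_stop, self.azimuth_step)

    def elevations(self) -> np.ndarray:
        return np.arange(self.elevation_start, self.elevation_stop, self.elevation_step)

    @property
    def n_angles(self) -> int:
        n = len(self.azimuths()) * len(self.elevations())
        if n == 0:
            raise ValueError("empty angular grid")
        return n

    def directions(self) -> tuple[np.ndarray, np.ndarray]:
        """All scan directions in scan order (elevation outer, azimuth inner).

        Returns ``(angles, dirs)``: an (N, 2) array of (azimuth, elevation)
        pairs and the matching (N, 3) array of unit (x, y, z) vectors.
        """
        az = self.azimuths()
        el = self.elevations()
        if len(az) == 0 or len(el) == 0:
            raise ValueError("empty angular grid")
        ee, aa = np.meshgrid(el, az, indexing="ij")
        angles = np.column_stack([aa.ravel(), ee.ravel()])
        ar = np.radians(angles[:, 0])
        er = np.radians(angles[:, 1])
        dirs = np.column_stack([np.sin(er) * np.cos(ar), np.sin(er) * np.sin(ar), np.cos(er)])
        return angles, dirs


@dataclass(frozen=True)
class RayConfig:
    """Ray geometry: total path length ``length`` (voxels), sampling step,
    and the sampling rule (nearest-voxel only).

    When ``length`` is None it defaults to ``round(sqrt(2) * window)`` so the
    ray spans the diagonal of the local analysis window.
    """

    length: int | None = None
    step: int = 1
    sampling: str = "nearest"

    def __post_init__(self) -> None:
        if self.sampling != "nearest":
            raise ValueError(f"unsupported sampling mode: {self.sampling!r}")
        if self.step < 1:
            raise ValueError("ray step must be >= 1")

    def resolved_length(self, window: int | None = None) -> int:
        if self.length is not None:
            return int(self.length)
        if window is None:
            raise ValueError("ray length unset and no window size given")
        return int(round(math.sqrt(2.0) * window))


def default_ray_length(window: int) -> int:
    """Ray length spanning the diagonal of a cubic window: round(sqrt(2)·N_W)."""
    return int(round(math.sqrt(2.0) * window))


# ---------------------------------------------------------------------------
# Ray sums
# ---------------------------------------------------------------------------

def _sample_offsets(dirs: np.ndarray, L: int, step: int) -> np.ndarray:
    """Integer voxel offsets of the ray samples for each direction.

    Sample j of direction k sits at the voxel nearest to ``l * d`` with
    ``l = -floor(L/2) .. +floor(L/2)`` (per-component round-half-up).  Since
    query points are integer voxel coordinates the nearest-voxel rule
    separates into point + offset exactly.
    """
    half = L // 2
    ls = np.arange(-half, half + 1, step, dtype=np.float64)
    # dirs is (n, 3) in (x, y, z); offsets stored (n, m, 3) as (z, y, x)
    pos = ls[None, :, None] * dirs[:, None, ::-1]
    return np.floor(pos + 0.5).astype(np.int32)


@njit(cache=True)
def _ray_sum_kernel(vol, z, y, x, offs):
    total = 0.0
    nz, ny, nx = vol.shape
    for j in range(offs.shape[0]):
        sz = z + offs[j, 0]
        sy = y + offs[j, 1]
        sx = x + offs[j, 2]
        if 0 <= sx < nx and 0 <= sy < ny and 0 <= sz < nz:
            total += vol[sz, sy, sx]
    return total


def ray_sum(volume: Volume, point, o: Orientation, cfg: RayConfig) -> float:
    """Discretized bidirectional line integral through ``point``.

    Samples at offsets l in {-floor(L/2), ..., +floor(L/2)} (step ``cfg.step``)
    along the orientation's direction; each sample reads the voxel nearest to
    ``point + l*d`` (per-component round-half-up) and samples outside the
    volume contribute 0.
    """
    z, y, x = (int(c) for c in point)
    nz, ny, nx = volume.shape
    if not (0 <= z < nz and 0 <= y < ny and 0 <= x < nx):
        raise ValueError(f"point {point} outside volume of shape {volume.shape}")
    d = direction_vector(o)
    offs = _sample_offsets(d[None, :], cfg.resolved_length(), cfg.step)[0]
    vol = np.ascontiguousarray(volume.data, dtype=np.float32)
    return float(_ray_sum_kernel(vol, z, y, x, offs))


def ray_sum_reference(volume: Volume, point, o: Orientation, cfg: RayConfig) -> float:
    """Pure-Python reference ray-sum with identical nearest-voxel arithmetic.

    Kept free of numpy vectorization so it can serve as an independent oracle
    for the JIT kernel.
    """
    z, y, x = (int(c) for c in point)
    nz, ny, nx = volume.shape
    if not (0 <= z < nz and 0 <= y < ny and 0 <= x < nx):
        raise ValueError(f"point {point} outside volume of shape {volume.shape}")
    a = math.radians(o.azimuth)
    e = math.radians(o.elevation)
    dx = math.sin(e) * math.cos(a)
    dy = math.sin(e) * math.sin(a)
    dz = math.cos(e)
    L = cfg.resolved_length()
    data = volume.data.astype(np.float32)
    total = 0.0
    for l in range(-(L // 2), L // 2 + 1, cfg.step):
        sx = x + math.floor(l * dx + 0.5)
        sy = y + math.floor(l * dy + 0.5)
        sz = z + math.floor(l * dz + 0.5)
        if 0 <= sx < nx and 0 <= sy < ny and 0 <= sz < nz:
            total += float(data[int(sz), int(sy), int(sx)])
    return total


# ---------------------------------------------------------------------------
# Orientation estimation
# ---------------------------------------------------------------------------

@njit(cache=True, parallel=True)
def _scan_kernel(vol, sites, offs):
    n_sites = sites.shape[0]
    n_dirs = offs.shape[0]
    n_samples = offs.shape[1]
    nz, ny, nx = vol.shape
    best_idx = np.empty(n_sites, dtype=np.int64)
    best_sum = np.empty(n_sites, dtype=np.float64)
    for s in prange(n_sites):
        z = sites[s, 0]
        y = sites[s, 1]
        x = sites[s, 2]
        bi = 0
        bs = -1.0
        for k in range(n_dirs):
            total = 0.0
            for j in range(n_samples):
                sz = z + offs[k, j, 0]
                sy = y + offs[k, j, 1]
                sx = x + offs[k, j, 2]
                if 0 <= sx < nx and 0 <= sy < ny and 0 <= sz < nz:
                    total += vol[sz, sy, sx]
            if total > bs:
                bs = total
                bi = k
        best_idx[s] = bi
        best_sum[s] = bs
    return best_idx, best_sum


def estimate_orientation(
    volume: Volume,
    point,
    grid: AngularGrid | None = None,
    cfg: RayConfig | None = None,
    window: int = 33,
) -> tuple[Orientation, float, bool]:
    """Exhaustive angular scan at one voxel.

    Returns ``(orientation, max_ray_sum, indeterminate)``.  Ties are broken by
    scan order (elevation outer ascending, azimuth inner ascending, first
    maximum wins); a winning elevation of 0° reports azimuth 0° (the Z-aligned
    pole is azimuth-degenerate).  The estimate is flagged indeterminate when
    the best ray-sum does not exceed the intensity at the point itself.
    """
    grid = grid or AngularGrid()
    cfg = cfg or RayConfig()
    sites = np.array([[int(c) for c in point]], dtype=np.int64)
    field_ = _scan_sites(volume, sites, grid, cfg, window)
    o = Orientation(field_.angles[0, 0], field_.angles[0, 1])
    return o, float(field_.score[0]), bool(field_.indeterminate[0])


def estimate_orientation_reference(volume: Volume, point, grid: AngularGrid, cfg: RayConfig):
    """Naive triple-loop scan used as the oracle for the JIT path."""
    angles, _ = grid.directions()
    best = None
    best_sum = -1.0
    for a, e in angles:
        s = ray_sum_reference(volume, point, Orientation(a, e), cfg)
        if s > best_sum:
            best_sum = s
            best = (a, e)
    az, el = best
    if el == 0.0:
        az = 0.0
    z, y, x = (int(c) for c in point)
    indeterminate = best_sum <= float(volume.data[z, y, x])
    return Orientation(az, el), best_sum, indeterminate


def _scan_sites(volume, sites, grid, cfg, window) -> OrientationField:
    nz, ny, nx = volume.shape
    if np.any(sites < 0) or np.any(sites >= np.array([nz, ny, nx])):
        raise ValueError("site coordinates fall outside the volume")
    L = cfg.resolved_length(window)
    angles, dirs = grid.directions()
    offs = np.ascontiguousarray(_sample_offsets(dirs, L, cfg.step))
    vol = np.ascontiguousarray(volume.data, dtype=np.float32)
    best_idx, best_sum = _scan_kernel(vol, sites, offs)
    out = angles[best_idx].copy()
    out[out[:, 1] == 0.0, 0] = 0.0  # Z-aligned pole: azimuth degenerate
    center_vals = vol[sites[:, 0], sites[:, 1], sites[:, 2]].astype(np.float64)
    indeterminate = best_sum <= center_vals
    return OrientationField(sites, out, indeterminate=indeterminate, score=best_sum)


def estimate_field(
    volume: Volume,
    sites,
    grid: AngularGrid | None = None,
    cfg: RayConfig | None = None,
    window: int = 33,
) -> OrientationField:
    """Estimate orientation at every site voxel of a skeleton.

    ``sites`` is a BinaryVolume / boolean mask (skeleton) or an (N, 3) array of
    (z, y, x) coordinates.  Rays are cast through ``volume`` — by default the
    skeleton itself is passed as both, matching the idea that the ray should
    accumulate medial-axis evidence; the segmented volume may be passed
    instead.  Site iteration order is z, y, x ascending and results are
    independent of any parallel partitioning of the sites.
    """
    grid = grid or AngularGrid()
    cfg = cfg or RayConfig()
    coords = _site_coords(sites)
    if len(coords) == 0:
        logger.warning("estimate_field called with no sites; returning empty field")
        return OrientationField(np.zeros((0, 3), dtype=np.int64), np.zeros((0, 2)))
    with log_stage(f"raycast field ({len(coords)} sites, window {window})"):
        return _scan_sites(volume, coords, grid, cfg, window)


def _site_coords(sites) -> np.ndarray:
    from .preprocess import BinaryVolume

    if isinstance(sites, BinaryVolume):
        mask = sites.data.astype(bool)
    elif isinstance(sites, Volume):
        mask = sites.data.astype(bool)
    elif isinstance(sites, np.ndarray) and sites.ndim == 3:
        mask = sites.astype(bool)
    else:
        return np.atleast_2d(np.asarray(sites, dtype=np.int64))
    return np.argwhere(mask).astype(np.int64)  # z,y,x ascending
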