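"""Ground-truth fibrous phantoms and the noise model applied to them.

Phantoms are binary volumes of rasterized straight circular cylinders
("fibers") that traverse the volume, with radii, inter-fiber gaps and
orientations drawn uniformly from configured ranges.  Each fiber carries its
exact continuous ground-truth orientation so downstream estimates can be
scored.  Contamination follows the fixed order: additive white Gaussian noise
(sigma_agn) first, Gaussian smoothing (sigma_smooth) second, applied to a
float copy of the binary volume without clipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import Volume, logger
from .raycast import Orientation, direction_vector


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic fibrous volume.

    Defaults reproduce the validation regime: a cube of straight fibers with
    radii 3–20 voxels, pairwise surface gaps 3–10 voxels, azimuths spanning
    [-90°, 90°) and elevations [0°, 90°].
    """

    volume_size: int = 512
    n_fibers: int = 70
    radius_range: tuple[float, float] = (3.0, 20.0)
    gap_range: tuple[float, float] = (3.0, 10.0)
    azimuth_range: tuple[float, float] = (-90.0, 90.0)
    elevation_range: tuple[float, float] = (0.0, 90.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("radius_range", self.radius_range), ("gap_range", self.gap_range)):
            if lo <= 0 or lo > hi:
                raise ValueError(f"{name} must be positive with min <= max, got {(lo, hi)}")
        alo, ahi = self.azimuth_range
        elo, ehi = self.elevation_range
        if not (-90.0 <= alo <= ahi <= 90.0):
            raise ValueError(f"azimuth_range must lie within [-90, 90], got {self.azimuth_range}")
        if not (0.0 <= elo <= ehi <= 90.0):
            raise ValueError(f"elevation_range must lie within [0, 90], got {self.elevation_range}")
        if self.radius_range[0] * 2 > self.volume_size:
            raise ValueError(
                f"minimum fiber radius {self.radius_range[0]} does not fit volume of size {self.volume_size}"
            )
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")


@dataclass
class FiberRecord:
    """Ground truth for one placed fiber.

    ``axis_voxels`` is the rasterized central axis (26-connected, within one
    voxel of the continuous line); ``orientation`` is the exact continuous
    angle pair, not a rasterized estimate.
    """

    center: tuple[float, float, float]  # (z, y, x) voxels
    orientation: Orientation
    radius: float
    axis_voxels: np.ndarray  # (n, 3) int, (z, y, x)
    gap: float = 3.0


@dataclass(frozen=True)
class NoiseConfig:
    """Additive Gaussian noise (sigma_agn) followed by Gaussian smoothing
    (sigma_smooth); a sigma of 0 skips that stage."""

    sigma_agn: float = 0.0
    sigma_smooth: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_agn < 0 or self.sigma_smooth < 0:
            raise ValueError("noise sigmas must be >= 0")


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _clip_axis_to_volume(center, u, half_length, size):
    """Parameter range [tmin, tmax] of the axis line inside the volume cube.

    ``center`` and ``u`` are (z, y, x); the cube is [0, size-1] per axis.
    Returns None when the line misses the cube.
    """
    tmin, tmax = -half_length, half_length
    for k in range(3):
        c, d = center[k], u[k]
        lo, hi = 0.0, size - 1.0
        if abs(d) < 1e-12:
            if not (lo <= c <= hi):
                return None
            continue
        t0, t1 = (lo - c) / d, (hi - c) / d
        if t0 > t1:
            t0, t1 = t1, t0
        tmin, tmax = max(tmin, t0), min(tmax, t1)
    if tmin > tmax:
        return None
    return tmin, tmax


def _segment_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between 3D segments [p0,p1] and [q0,q1]."""
    p0, p1, q0, q1 = (np.asarray(v, dtype=float) for v in (p0, p1, q0, q1))
    u = p1 - p0
    v = q1 - q0
    w = p0 - q0
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    denom = a * c - b * b
    if denom > 1e-12:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > 1e-12 else 0.0
    t = np.clip(t, 0.0, 1.0)
    # re-project s for the clamped t
    if a > 1e-12:
        s = np.clip((b * t - d) / a, 0.0, 1.0)
    return float(np.linalg.norm(w + s * u - t * v))


def _rasterize_cylinder(mask, center, u, radius, t_range):
    """Set voxels whose center lies within ``radius`` of the axis segment."""
    size = mask.shape[0]
    cz, cy, cx = center
    uz, uy, ux = u
    z = (np.arange(size, dtype=np.float32) - cz)[:, None, None]
    y = (np.arange(size, dtype=np.float32) - cy)[None, :, None]
    x = (np.arange(size, dtype=np.float32) - cx)[None, None, :]
    t = z * uz + y * uy + x * ux
    d2 = (z * z + y * y + x * x) - t * t
    tmin, tmax = t_range
    mask |= (d2 <= radius * radius) & (t >= tmin) & (t <= tmax)


def _axis_voxels(center, u, t_range, size) -> np.ndarray:
    """Rasterize the central axis as a 26-connected voxel chain.

    The parameter range is shrunk by one voxel at each end so that rounding
    never produces an axis voxel beyond the cylinder's end caps.
    """
    tmin, tmax = t_range
    if tmax - tmin > 4.0:
        tmin, tmax = tmin + 1.0, tmax - 1.0
    n = max(2, int(np.ceil((tmax - tmin) / 0.5)) + 1)
    ts = np.linspace(tmin, tmax, n)
    pts = np.floor(np.asarray(center)[None, :] + ts[:, None] * np.asarray(u)[None, :] + 0.5).astype(np.int64)
    np.clip(pts, 0, size - 1, out=pts)
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
    return pts[keep]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> tuple[Volume, list[FiberRecord]]:
    """Generate a binary fibrous phantom with per-fiber ground truth.

    Fibers are straight cylinders spanning the volume (half-length = the cube
    diagonal / 2, clipped to the cube).  Placement is rejection sampling:
    orientation, radius, gap and center are drawn uniformly; a candidate is
    accepted iff its surface-to-surface distance to every accepted fiber is at
    least its sampled gap.  Up to 100 attempts are made per fiber; fewer
    placed fibers than requested is logged as a warning, never an error.
    The result is fully determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.volume_size
    half_length = np.sqrt(3.0) * size / 2.0
    mask = np.zeros((size, size, size), dtype=bool)
    fibers: list[FiberRecord] = []
    attempts_per_fiber = 100

    for _ in range(spec.n_fibers):
        for _attempt in range(attempts_per_fiber):
            az = rng.uniform(*spec.azimuth_range)
            el = rng.uniform(*spec.elevation_range)
            radius = rng.uniform(*spec.radius_range)
            gap = rng.uniform(*spec.gap_range)
            center = rng.uniform(0, size - 1, size=3)  # (z, y, x)
            o = Orientation(min(az, float(np.nextafter(90.0, 0.0))), el)
            dx, dy, dz = direction_vector(o)
            u = np.array([dz, dy, dx])  # (z, y, x) component order
            t_range = _clip_axis_to_volume(center, u, half_length, size)
            if t_range is None or t_range[1] - t_range[0] < 2.0:
                continue
            seg = (center + t_range[0] * u, center + t_range[1] * u)
            ok = True
            for fb in fibers:
                other = _fiber_segment(fb, size, half_length)
                dist = _segment_distance(seg[0], seg[1], other[0], other[1])
                surface = dist - radius - fb.radius
                if surface < max(gap, fb.gap):
                    ok = False
                    break
            if not ok:
                continue
            _rasterize_cylinder(mask, center, u, radius, t_range)
            axis = _axis_voxels(center, u, t_range, size)
            fibers.append(
                FiberRecord(
                    center=tuple(center),
                    orientation=o,
                    radius=radius,
                    axis_voxels=axis,
                    gap=gap,
                )
            )
            break
        else:
            logger.warning(
                "phantom placement: %d/%d fibers placed after %d attempts each",
                len(fibers), spec.n_fibers, attempts_per_fiber,
            )
            break

    return Volume(mask.astype(np.uint8)), fibers


def _fiber_segment(fb: FiberRecord, size: int, half_length: float):
    dx, dy, dz = direction_vector(fb.orientation)
    u = np.array([dz, dy, dx])
    c = np.asarray(fb.center)
    t_range = _clip_axis_to_volume(c, u, half_length, size)
    return c + t_range[0] * u, c + t_range[1] * u


def truth_axis_table(fibers: list[FiberRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated ground-truth axis voxels and their fiber indices."""
    if not fibers:
        return np.zeros((0, 3), dtype=np.int64), np.zeros(0, dtype=np.int64)
    coords = np.concatenate([fb.axis_voxels for fb in fibers])
    idx = np.concatenate([np.full(len(fb.axis_voxels), i, dtype=np.int64) for i, fb in enumerate(fibers)])
    return coords, idx


# ---------------------------------------------------------------------------
# Contamination
# ---------------------------------------------------------------------------

def contaminate(volume: Volume, noise: NoiseConfig) -> Volume:
    """Apply additive Gaussian noise, then Gaussian smoothing.

    Operates on a float copy of the input; intensities are not clipped, so a
    binary phantom keeps unit signal amplitude against noise of the stated
    sigma.  Deterministic given ``noise.seed``.
    """
    data = volume.data.astype(np.float32, copy=True)
    if noise.sigma_agn > 0:
        rng = np.random.default_rng(noise.seed)
        data += rng.normal(0.0, noise.sigma_agn, size=data.shape).astype(np.float32)
    if noise.sigma_smooth > 0:
        data = ndimage.gaussian_filter(data, sigma=noise.sigma_smooth)
    return Volume(data, voxel_size=volume.voxel_size, origin=volume.origin)
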