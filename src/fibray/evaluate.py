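"""Accuracy evaluation: angular errors, noise/window experiments, histograms,
polar error maps and analytic operation counts.

Error convention: elevation error is the plain absolute difference; azimuth
error is wrapped with period 180° (min(|d|, 180-|d|)) because the azimuth of
an undirected axis is only defined modulo 180°.  Estimated skeleton sites are
matched to the nearest ground-truth fiber-axis voxel within a small radius;
sites without a match (over-segmentation debris) are counted separately and
excluded from the error means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import OrientationField, Volume, log_stage, logger
from .preprocess import median3d, otsu_segment, skeletonize3d
from .raycast import AngularGrid, Orientation, RayConfig, estimate_field
from .synthetic import NoiseConfig, PhantomSpec, contaminate, generate_phantom, truth_axis_table
from .tensor import estimate_field_tensor

MATCH_RADIUS_VOXELS = 2.0


# ---------------------------------------------------------------------------
# Angular errors
# ---------------------------------------------------------------------------

def angular_errors(estimate: Orientation, truth: Orientation) -> tuple[float, float]:
    """Component-wise absolute angular errors (azimuth, elevation) in degrees.

    Azimuth uses the period-180 wrap, so -88° vs +88° is a 4° error; both
    components land in [0, 90].
    """
    da = abs(estimate.azimuth - truth.azimuth)
    az_err = min(da, 180.0 - da)
    el_err = abs(estimate.elevation - truth.elevation)
    return az_err, el_err


def _angular_errors_array(angles: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    da = np.abs(angles[:, 0] - truth[:, 0])
    az = np.minimum(da, 180.0 - da)
    el = np.abs(angles[:, 1] - truth[:, 1])
    return az, el


# ---------------------------------------------------------------------------
# Site matching and reports
# ---------------------------------------------------------------------------

def match_field_to_truth(field_: OrientationField, fibers, max_dist: float = MATCH_RADIUS_VOXELS):
    """Attach ground-truth angles to a field by nearest fiber-axis voxel.

    A site matches the fiber whose rasterized axis voxel is nearest within
    ``max_dist`` (Euclidean voxels); unmatched sites keep NaN truth.  Returns
    ``(field_with_truth, n_unmatched)``.
    """
    axis_coords, fiber_idx = truth_axis_table(fibers)
    if len(axis_coords) == 0:
        raise ValueError("no ground-truth fibers to match against")
    tree = cKDTree(axis_coords)
    dist, nearest = tree.query(field_.coords, distance_upper_bound=max_dist)
    matched = np.isfinite(dist)
    truth = np.full((len(field_), 2), np.nan)
    fiber_of = np.full(len(field_), -1, dtype=np.int64)
    if matched.any():
        fibs = fiber_idx[nearest[matched]]
        fiber_of[matched] = fibs
        truth[matched, 0] = [fibers[i].orientation.azimuth for i in fibs]
        truth[matched, 1] = [fibers[i].orientation.elevation for i in fibs]
    n_unmatched = int((~matched).sum())
    out = OrientationField(
        field_.coords, field_.angles, truth=truth,
        indeterminate=field_.indeterminate, score=field_.score,
    )
    return out, n_unmatched


@dataclass
class ErrorReport:
    """Per-site absolute angular errors with their summary statistics."""

    azimuth_errors: np.ndarray
    elevation_errors: np.ndarray
    n_sites: int
    n_excluded: int = 0
    config: dict = dataclass_field(default_factory=dict)

    @property
    def mean_azimuth(self) -> float:
        return float(self.azimuth_errors.mean())

    @property
    def mean_elevation(self) -> float:
        return float(self.elevation_errors.mean())

    @property
    def std_azimuth(self) -> float:
        return float(self.azimuth_errors.std())

    @property
    def std_elevation(self) -> float:
        return float(self.elevation_errors.std())

    @property
    def sum_azimuth(self) -> float:
        return float(self.azimuth_errors.sum())

    @property
    def sum_elevation(self) -> float:
        return float(self.elevation_errors.sum())

    def to_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "n_excluded": self.n_excluded,
            "mean_azimuth_error_deg": self.mean_azimuth,
            "mean_elevation_error_deg": self.mean_elevation,
            "std_azimuth_error_deg": self.std_azimuth,
            "std_elevation_error_deg": self.std_elevation,
            "sum_azimuth_error_deg": self.sum_azimuth,
            "sum_elevation_error_deg": self.sum_elevation,
            "config": self.config,
        }


def evaluate_field(field_: OrientationField, config: dict | None = None) -> ErrorReport:
    """Aggregate angular errors of a field that carries ground truth.

    Sites with NaN truth (unmatched) or flagged indeterminate are excluded
    from the statistics and reported in ``n_excluded``.
    """
    if field_.truth is None:
        raise ValueError("field carries no ground truth to evaluate against")
    valid = np.isfinite(field_.truth).all(axis=1) & ~field_.indeterminate
    valid &= np.isfinite(field_.angles).all(axis=1)
    if not valid.any():
        raise ValueError("no valid (matched, determinate) sites to evaluate")
    az, el = _angular_errors_array(field_.angles[valid], field_.truth[valid])
    return ErrorReport(
        azimuth_errors=az,
        elevation_errors=el,
        n_sites=int(valid.sum()),
        n_excluded=int((~valid).sum()),
        config=dict(config or {}),
    )


# ---------------------------------------------------------------------------
# Workflow runners
# ---------------------------------------------------------------------------

def to_odd(window: int) -> int:
    """Centered cubic windows need an odd side: evens map to the next odd."""
    return window if window % 2 == 1 else window + 1


def run_workflow(
    phantom: Volume,
    fibers,
    *,
    sigma_agn: float = 0.0,
    sigma_smooth: float = 0.0,
    noise_seed: int = 0,
    window: int = 33,
    grid: AngularGrid | None = None,
    methods: tuple[str, ...] = ("raycast", "tensor"),
    ray_input: str = "skeleton",
) -> dict:
    """Full analysis chain on a phantom: contaminate -> median -> Otsu ->
    thinning -> orientation estimation -> truth matching.

    Returns a dict with the matched fields and error reports per method plus
    the intermediate segmentation/skeleton.
    """
    window = to_odd(window)
    grid = grid or AngularGrid()
    vol = phantom
    if sigma_agn > 0 or sigma_smooth > 0:
        vol = contaminate(phantom, NoiseConfig(sigma_agn, sigma_smooth, seed=noise_seed))
    med = median3d(vol, size=3)
    seg = otsu_segment(med, mode="global")
    skel = skeletonize3d(seg)
    out = {"segmented": seg, "skeleton": skel, "reports": {}, "fields": {}}
    config_base = {
        "window": window,
        "sigma_agn": sigma_agn,
        "sigma_smooth": sigma_smooth,
    }
    for method in methods:
        if method == "raycast":
            ray_vol = skel.as_volume() if ray_input == "skeleton" else seg.as_volume()
            fld = estimate_field(ray_vol, skel, grid, RayConfig(), window=window)
        elif method == "tensor":
            fld = estimate_field_tensor(seg, skel, window=window)
        else:
            raise ValueError(f"unknown method {method!r}")
        matched, n_unmatched = match_field_to_truth(fld, fibers)
        report = evaluate_field(matched, config={**config_base, "method": method})
        report.config["n_unmatched"] = n_unmatched
        out["fields"][method] = matched
        out["reports"][method] = report
    return out


def window_sweep(
    phantom: Volume,
    fibers,
    method: str,
    windows,
    *,
    grid: AngularGrid | None = None,
    sigma_agn: float = 0.0,
    sigma_smooth: float = 0.0,
    noise_seed: int = 0,
) -> dict:
    """Accuracy as a function of window size for one method.

    Preprocessing does not depend on the window, so segmentation and skeleton
    are computed once and each window re-runs only the estimation stage.
    Even windows are rounded up to the next odd with the mapping recorded.
    Returns the report series and the window minimizing the summed
    (azimuth + elevation) error.
    """
    windows = list(windows)
    if windows != sorted(windows):
        raise ValueError("windows must be sorted ascending")
    grid = grid or AngularGrid()
    vol = phantom
    if sigma_agn > 0 or sigma_smooth > 0:
        vol = contaminate(phantom, NoiseConfig(sigma_agn, sigma_smooth, seed=noise_seed))
    med = median3d(vol, size=3)
    seg = otsu_segment(med, mode="global")
    skel = skeletonize3d(seg)

    series = []
    for w in windows:
        w_odd = to_odd(w)
        if method == "raycast":
            fld = estimate_field(skel.as_volume(), skel, grid, RayConfig(), window=w_odd)
        elif method == "tensor":
            fld = estimate_field_tensor(seg, skel, window=w_odd)
        else:
            raise ValueError(f"unknown method {method!r}")
        matched, n_unmatched = match_field_to_truth(fld, fibers)
        report = evaluate_field(matched, config={"window": w_odd, "requested_window": w, "method": method})
        report.config["n_unmatched"] = n_unmatched
        series.append(report)
    summed = [r.mean_azimuth + r.mean_elevation for r in series]
    best = int(np.argmin(summed))
    return {
        "windows": windows,
        "windows_odd": [to_odd(w) for w in windows],
        "reports": series,
        "best_window": to_odd(windows[best]),
        "best_index": best,
    }


def table1_experiment(
    sigmas,
    base_spec: PhantomSpec,
    window: int = 33,
    *,
    grid: AngularGrid | None = None,
    sigma_smooth: float = 1.0,
    seeds=(0,),
) -> dict:
    """Noise-robustness experiment: both methods across a sigma_agn ladder.

    For each seed a phantom is generated once; for each sigma the phantom is
    contaminated (noiseless rows use the raw phantom, noisy rows additionally
    get Gaussian smoothing of ``sigma_smooth``), pushed through the full
    workflow, and both methods are scored.  The summary table carries the
    per-method mean absolute errors averaged over seeds and the
    tensor-minus-raycast difference columns.
    """
    grid = grid or AngularGrid()
    rows = []
    detail = {}
    for seed in seeds:
        spec = PhantomSpec(
            volume_size=base_spec.volume_size,
            n_fibers=base_spec.n_fibers,
            radius_range=base_spec.radius_range,
            gap_range=base_spec.gap_range,
            azimuth_range=base_spec.azimuth_range,
            elevation_range=base_spec.elevation_range,
            seed=seed,
        )
        with log_stage(f"phantom generation (seed {seed})"):
            phantom, fibers = generate_phantom(spec)
        for sigma in sigmas:
            smooth = sigma_smooth if sigma > 0 else 0.0
            noise_seed = (int(seed) * 9973 + int(round(sigma * 10))) % (2**31)
            res = run_workflow(
                phantom, fibers,
                sigma_agn=sigma, sigma_smooth=smooth, noise_seed=noise_seed,
                window=window, grid=grid,
            )
            ray, ten = res["reports"]["raycast"], res["reports"]["tensor"]
            detail[(seed, sigma)] = res["reports"]
            rows.append(
                {
                    "seed": seed,
                    "sigma_agn": sigma,
                    "raycast_azimuth": ray.mean_azimuth,
                    "raycast_elevation": ray.mean_elevation,
                    "tensor_azimuth": ten.mean_azimuth,
                    "tensor_elevation": ten.mean_elevation,
                }
            )
    per_seed = pd.DataFrame(rows)
    table = per_seed.groupby("sigma_agn", as_index=False).mean().drop(columns="seed")
    table["diff_azimuth"] = table["tensor_azimuth"] - table["raycast_azimuth"]
    table["diff_elevation"] = table["tensor_elevation"] - table["raycast_elevation"]
    return {"table": table, "per_seed": per_seed, "detail": detail}


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------

AZIMUTH_BIN_EDGES = np.arange(-90.0, 90.0 + 5.0, 5.0)
ELEVATION_BIN_EDGES = np.arange(0.0, 90.0 + 5.0, 5.0)


@dataclass
class PolarHeatmap:
    """Mean azimuth error + mean elevation error per ground-truth angular bin.

    5° bins over azimuth [-90, 90] x elevation [0, 90]; empty bins hold NaN
    (distinct from a true zero error), and the intended display scale is
    logarithmic.
    """

    values: np.ndarray  # (n_elevation_bins, n_azimuth_bins)
    azimuth_edges: np.ndarray
    elevation_edges: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=[f"el_{e:g}" for e in self.elevation_edges[:-1]],
            columns=[f"az_{a:g}" for a in self.azimuth_edges[:-1]],
        )


def polar_heatmap(field_: OrientationField) -> PolarHeatmap:
    """Bin sites by ground-truth angles; cell = mean az error + mean el error."""
    if field_.truth is None or len(field_) == 0:
        raise ValueError("polar_heatmap needs a non-empty field with ground truth")
    valid = np.isfinite(field_.truth).all(axis=1) & ~field_.indeterminate
    valid &= np.isfinite(field_.angles).all(axis=1)
    az_err, el_err = _angular_errors_array(field_.angles[valid], field_.truth[valid])
    ta, te = field_.truth[valid, 0], field_.truth[valid, 1]
    ai = np.clip(np.digitize(ta, AZIMUTH_BIN_EDGES) - 1, 0, len(AZIMUTH_BIN_EDGES) - 2)
    ei = np.clip(np.digitize(te, ELEVATION_BIN_EDGES) - 1, 0, len(ELEVATION_BIN_EDGES) - 2)
    shape = (len(ELEVATION_BIN_EDGES) - 1, len(AZIMUTH_BIN_EDGES) - 1)
    sums_az = np.zeros(shape)
    sums_el = np.zeros(shape)
    counts = np.zeros(shape)
    np.add.at(sums_az, (ei, ai), az_err)
    np.add.at(sums_el, (ei, ai), el_err)
    np.add.at(counts, (ei, ai), 1)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums_az / np.maximum(counts, 1) + sums_el / np.maximum(counts, 1), np.nan)
    return PolarHeatmap(values, AZIMUTH_BIN_EDGES, ELEVATION_BIN_EDGES)


def orientation_histograms(field_: OrientationField) -> tuple[np.ndarray, np.ndarray]:
    """Fixed 5°-bin histograms of the estimated azimuths and elevations.

    Returns ``(azimuth_counts, elevation_counts)``; counts sum to the number
    of sites with finite angles.
    """
    if len(field_) == 0:
        raise ValueError("orientation_histograms needs a non-empty field")
    finite = np.isfinite(field_.angles).all(axis=1)
    az = np.clip(field_.angles[finite, 0], -90.0, np.nextafter(90.0, 0))
    el = np.clip(field_.angles[finite, 1], 0.0, 90.0)
    az_counts, _ = np.histogram(az, bins=AZIMUTH_BIN_EDGES)
    el_counts, _ = np.histogram(el, bins=ELEVATION_BIN_EDGES)
    return az_counts, el_counts


# ---------------------------------------------------------------------------
# Analytic operation counts and the window-size factor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplexityParams:
    """Symbolic sizes of one local estimation: angular grid (N_theta x N_phi),
    window side N_W, and tensor matrix size N_d."""

    n_theta: int = 180
    n_phi: int = 90
    n_w: int = 33
    n_d: int = 3

    def __post_init__(self) -> None:
        if min(self.n_theta, self.n_phi, self.n_w, self.n_d) < 1:
            raise ValueError("complexity parameters must be positive")


def op_count_raycast(p: ComplexityParams) -> float:
    """Arithmetic operations of one ray-casting estimation:
    (N_theta * N_phi) * sqrt(N_W^2 + N_W^2) — every ray spans the window
    diagonal."""
    return (p.n_theta * p.n_phi) * math.sqrt(p.n_w**2 + p.n_w**2)


def op_count_tensor(p: ComplexityParams) -> float:
    """Arithmetic operations of one tensor estimation:
    N_W^2 * (10/3 * N_d^3 + N_d^2) + (6 * N_d^2 + N_d)."""
    return p.n_w**2 * (10.0 / 3.0 * p.n_d**3 + p.n_d**2) + (6 * p.n_d**2 + p.n_d)


def window_radius_factor(window: float, mean_radius: float) -> float:
    """Ratio of the optimal window side to the mean fiber diameter
    (window / (2 * mean_radius))."""
    return window / (2.0 * mean_radius)


def predict_window_px(diameter_um: float, resolution_um: float, factor: float) -> int:
    """Optimal window in pixels for a physical fiber diameter:
    round(diameter / resolution * factor)."""
    return int(round(diameter_um / resolution_um * factor))


def unify_windows(windows) -> int:
    """Average the per-method optimal windows into one shared size."""
    return int(round(float(np.mean(list(windows)))))
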