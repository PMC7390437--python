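"""Volume and orientation-field I/O.

Volumes are dense 3D scalar grids stored index order (z, y, x): page *i* of a
multipage TIFF is the slice ``data[i]``.  The alternative on-disk form is a raw
little-endian binary block with a YAML sidecar declaring ``shape``, ``dtype``
and ``voxel_size_um``.  Orientation fields are written as plain CSV with
0-based voxel coordinates.
"""

from __future__ import annotations

import logging
import sys
import time
from contextlib import contextmanager
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("fibray")

ORIENTATION_COLUMNS = ["x", "y", "z", "azimuth_deg", "elevation_deg"]
TRUTH_COLUMNS = ["true_azimuth_deg", "true_elevation_deg"]


def configure_logging(level: int = logging.INFO) -> None:
    """Route package logs to stderr; results stay on stdout/files."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


@contextmanager
def log_stage(name: str) -> Iterator[None]:
    """Log wall-clock time of a pipeline stage at INFO."""
    t0 = time.perf_counter()
    logger.info("stage %s: start", name)
    yield
    logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)


# ---------------------------------------------------------------------------
# Volume
# ---------------------------------------------------------------------------

@dataclass
class Volume:
    """A dense 3D scalar grid with isotropic voxel spacing.

    Parameters
    ----------
    data
        3D array, index order ``(z, y, x)``.
    voxel_size
        Physical voxel edge length in micrometres (isotropic).
    origin
        Integer voxel offset of this grid inside a parent volume, ``(z, y, x)``.
    """

    data: np.ndarray
    voxel_size: float = 1.0
    origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3D with all dimensions >= 1, got shape {self.data.shape}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def astype_float(self) -> "Volume":
        """Promote to float32 for arithmetic stages (copy only when needed)."""
        if np.issubdtype(self.data.dtype, np.floating):
            return self
        return replace(self, data=self.data.astype(np.float32))


def read_volume(path: str | Path, format: str | None = None) -> Volume:
    """Read a volume from a multipage TIFF stack or a raw+sidecar pair.

    ``format`` is ``"tiff_stack"`` or ``"raw"``; by default it is inferred
    from the file suffix (``.raw`` -> raw, anything else -> TIFF).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    if format is None:
        format = "raw" if path.suffix == ".raw" else "tiff_stack"
    if format == "tiff_stack":
        with tifffile.TiffFile(path) as tif:
            shapes = {p.shape for p in tif.pages}
            if len(shapes) > 1:
                raise ValueError(f"inconsistent page shapes in {path}: {sorted(shapes)}")
            data = tif.asarray()
            voxel_size = 1.0
            desc = tif.pages[0].description or ""
        if data.ndim == 2:
            data = data[None]
        meta = _parse_yaml_description(desc)
        if "voxel_size_um" in meta:
            voxel_size = float(meta["voxel_size_um"])
        return Volume(data, voxel_size=voxel_size)
    if format == "raw":
        sidecar = path.with_suffix(path.suffix + ".yaml")
        if not sidecar.exists():
            raise FileNotFoundError(f"raw volume requires sidecar metadata: {sidecar}")
        meta = yaml.safe_load(sidecar.read_text())
        shape = tuple(int(s) for s in meta["shape"])
        dtype = np.dtype(meta["dtype"])
        raw = np.fromfile(path, dtype=dtype)
        if raw.size != int(np.prod(shape)):
            raise ValueError(
                f"raw file {path} holds {raw.size} values, expected {int(np.prod(shape))} for shape {shape}"
            )
        return Volume(raw.reshape(shape), voxel_size=float(meta.get("voxel_size_um", 1.0)))
    raise ValueError(f"unknown volume format: {format!r}")


def _parse_yaml_description(desc: str) -> dict:
    if not desc.strip():
        return {}
    try:
        meta = yaml.safe_load(desc)
        return meta if isinstance(meta, dict) else {}
    except yaml.YAMLError:
        return {}


def write_volume(volume: Volume, path: str | Path, format: str | None = None) -> None:
    """Write a volume losslessly for integer data; floats are stored as 32-bit."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if format is None:
        format = "raw" if path.suffix == ".raw" else "tiff_stack"
    data = volume.data
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    if format == "tiff_stack":
        desc = yaml.safe_dump({"voxel_size_um": float(volume.voxel_size)})
        tifffile.imwrite(path, data, description=desc, photometric="minisblack")
    elif format == "raw":
        data.tofile(path)
        sidecar = path.with_suffix(path.suffix + ".yaml")
        sidecar.write_text(
            yaml.safe_dump(
                {
                    "shape": [int(s) for s in data.shape],
                    "dtype": data.dtype.name,
                    "voxel_size_um": float(volume.voxel_size),
                }
            )
        )
    else:
        raise ValueError(f"unknown volume format: {format!r}")


# ---------------------------------------------------------------------------
# Orientation field
# ---------------------------------------------------------------------------

@dataclass
class OrientationField:
    """Sparse per-voxel orientation estimates keyed by voxel coordinate.

    ``coords`` holds (z, y, x) 0-based voxel indices, one row per estimated
    site; ``angles`` the matching (azimuth, elevation) pairs in degrees.
    ``truth`` optionally carries ground-truth angles (NaN where unknown) and
    ``indeterminate`` flags sites whose best ray-sum did not exceed the value
    at the site itself (no directional evidence).
    """

    coords: np.ndarray
    angles: np.ndarray
    truth: np.ndarray | None = None
    indeterminate: np.ndarray | None = None
    score: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=np.int64))
        self.angles = np.atleast_2d(np.asarray(self.angles, dtype=np.float64))
        if self.coords.shape[0] != self.angles.shape[0]:
            raise ValueError("coords and angles row counts differ")
        if self.truth is not None:
            self.truth = np.atleast_2d(np.asarray(self.truth, dtype=np.float64))
        if self.indeterminate is None:
            self.indeterminate = np.zeros(len(self.coords), dtype=bool)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def has_truth(self) -> bool:
        return self.truth is not None

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "x": self.coords[:, 2],
                "y": self.coords[:, 1],
                "z": self.coords[:, 0],
                "azimuth_deg": self.angles[:, 0],
                "elevation_deg": self.angles[:, 1],
            }
        )
        if self.truth is not None:
            df["true_azimuth_deg"] = self.truth[:, 0]
            df["true_elevation_deg"] = self.truth[:, 1]
        return df


def write_orientation_field(field_: OrientationField, path: str | Path) -> None:
    """Write an orientation field as CSV (columns x,y,z,azimuth_deg,elevation_deg)."""
    if len(field_) == 0:
        raise ValueError("refusing to write an empty orientation field")
    field_.to_dataframe().to_csv(path, index=False)


def read_orientation_field(path: str | Path) -> OrientationField:
    df = pd.read_csv(path)
    coords = df[["z", "y", "x"]].to_numpy(dtype=np.int64)
    angles = df[["azimuth_deg", "elevation_deg"]].to_numpy(dtype=np.float64)
    truth = None
    if set(TRUTH_COLUMNS) <= set(df.columns):
        truth = df[TRUTH_COLUMNS].to_numpy(dtype=np.float64)
    return OrientationField(coords, angles, truth=truth)


# ---------------------------------------------------------------------------
# Phantom persistence (volume + per-fiber ground truth)
# ---------------------------------------------------------------------------

def save_phantom(path: str | Path, volume: Volume, fibers: list) -> None:
    """Persist a phantom and its ground truth to HDF5.

    Layout: dataset ``volume`` (uint8), group ``fibers`` with per-fiber
    scalar table and a concatenated ``axis_voxels`` dataset indexed by
    ``axis_offsets``.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("volume", data=volume.data.astype(np.uint8), compression="gzip")
        f.attrs["voxel_size_um"] = float(volume.voxel_size)
        g = f.create_group("fibers")
        g.create_dataset("center", data=np.array([fb.center for fb in fibers], dtype=np.float64))
        g.create_dataset(
            "orientation",
            data=np.array([(fb.orientation.azimuth, fb.orientation.elevation) for fb in fibers]),
        )
        g.create_dataset("radius", data=np.array([fb.radius for fb in fibers], dtype=np.float64))
        axes = [fb.axis_voxels for fb in fibers]
        offsets = np.cumsum([0] + [len(a) for a in axes])
        g.create_dataset(
            "axis_voxels",
            data=np.concatenate(axes) if axes else np.zeros((0, 3), dtype=np.int64),
        )
        g.create_dataset("axis_offsets", data=offsets)


def load_phantom(path: str | Path):
    """Load a phantom saved by :func:`save_phantom`; returns (Volume, fibers)."""
    from .synthetic import FiberRecord
    from .raycast import Orientation

    with h5py.File(path, "r") as f:
        volume = Volume(f["volume"][...], voxel_size=float(f.attrs.get("voxel_size_um", 1.0)))
        g = f["fibers"]
        centers = g["center"][...]
        oris = g["orientation"][...]
        radii = g["radius"][...]
        axis = g["axis_voxels"][...]
        off = g["axis_offsets"][...]
    fibers = [
        FiberRecord(
            center=tuple(centers[i]),
            orientation=Orientation(float(oris[i, 0]), float(oris[i, 1])),
            radius=float(radii[i]),
            axis_voxels=axis[off[i] : off[i + 1]],
        )
        for i in range(len(radii))
    ]
    return volume, fibers
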