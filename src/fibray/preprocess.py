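"""Workflow stages ahead of orientation estimation.

The standard μCT analysis chain: a 3×3×3 median filter against speckle noise,
Otsu thresholding into a binary fiber mask, and topology-preserving 3D
thinning of the mask down to a one-voxel-wide medial axis whose voxels serve
as orientation-estimation sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _skimage_skeletonize

from .io import Volume, log_stage, logger


@dataclass
class BinaryVolume:
    """Strictly {0,1}-valued volume; ``provenance`` is 'segmented' or 'skeleton'."""

    data: np.ndarray
    provenance: str = "segmented"
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"binary volume must be {{0,1}}-valued, found values {vals[:5]}")
        self.data = self.data.astype(np.uint8)
        if self.provenance not in ("segmented", "skeleton"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def as_volume(self) -> Volume:
        return Volume(self.data, voxel_size=self.voxel_size)

    def coords(self) -> np.ndarray:
        """Foreground voxel coordinates, (z, y, x) ascending."""
        return np.argwhere(self.data > 0).astype(np.int64)


def median3d(volume: Volume, size: int = 3) -> Volume:
    """Cubic median filter with edge replication at the borders.

    ``size`` must be odd so the window is centered; size 1 is the identity.
    """
    if size % 2 == 0 or size < 1:
        raise ValueError(f"median filter size must be odd and >= 1, got {size}")
    with log_stage(f"median3d (size {size})"):
        out = ndimage.median_filter(volume.data, size=size, mode="nearest")
    return Volume(out, voxel_size=volume.voxel_size, origin=volume.origin)


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold over an ``nbins``-bin histogram.

    Maximizes the between-class variance omega0*omega1*(mu0-mu1)^2 over all
    histogram split points; returns the bin center of the maximizing split
    (ties -> first in ascending order).
    """
    values = np.asarray(values).ravel()
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise ValueError("degenerate input: constant volume has no Otsu threshold")
    hist, edges = np.histogram(values, bins=nbins, range=(vmin, vmax))
    centers = (edges[:-1] + edges[1:]) / 2.0
    hist = hist.astype(np.float64)
    w0 = np.cumsum(hist)
    w1 = w0[-1] - w0
    sum0 = np.cumsum(hist * centers)
    mu_total = sum0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = sum0 / w0
        mu1 = (mu_total - sum0) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between[~np.isfinite(var_between)] = -np.inf
    # split after bin k: classes are bins [0..k] and [k+1..]; last split is void
    idx = int(np.argmax(var_between[:-1]))
    return float(centers[idx])


def otsu_segment(volume: Volume, mode: str = "global") -> BinaryVolume:
    """Threshold a volume into a binary fiber mask by Otsu's criterion.

    ``global`` uses one threshold for the whole volume; ``per_slice``
    thresholds each z-slice independently (the workflow used for stacks whose
    illumination drifts slice to slice).  Voxels strictly above the threshold
    map to 1.
    """
    if mode not in ("global", "per_slice"):
        raise ValueError(f"unknown Otsu mode {mode!r}")
    with log_stage(f"otsu_segment ({mode})"):
        if mode == "global":
            t = otsu_threshold(volume.data)
            binary = (volume.data > t).astype(np.uint8)
        else:
            binary = np.zeros(volume.shape, dtype=np.uint8)
            for z in range(volume.shape[0]):
                sl = volume.data[z]
                if sl.min() == sl.max():
                    logger.warning("otsu_segment: slice %d constant, left empty", z)
                    continue
                binary[z] = sl > otsu_threshold(sl)
    return BinaryVolume(binary, provenance="segmented", voxel_size=volume.voxel_size)


def skeletonize3d(binary: BinaryVolume) -> BinaryVolume:
    """Extract the 1-voxel-wide medial axis by 3D topology-preserving thinning.

    Delegates to the Lee-style iterative thinning (removal of simple border
    points) behind ``skimage.morphology.skeletonize``.  The skeleton is a
    voxelwise subset of the input mask; connected components of non-touching
    structures are preserved.  An empty mask yields an empty skeleton.
    """
    if binary.provenance != "segmented":
        raise ValueError("skeletonize3d expects a segmentation, not an existing skeleton")
    if binary.data.max() == 0:
        return BinaryVolume(np.zeros_like(binary.data), provenance="skeleton", voxel_size=binary.voxel_size)
    with log_stage("skeletonize3d"):
        sk = _skimage_skeletonize(binary.data.astype(bool))
    return BinaryVolume(sk.astype(np.uint8), provenance="skeleton", voxel_size=binary.voxel_size)
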