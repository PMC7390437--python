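import numpy as np
import pytest

from fibray import AngularGrid, Orientation, PhantomSpec, Volume, generate_phantom


@pytest.fixture(scope="session")
def z_line_volume() -> Volume:
    """9^3 volume with a single-voxel line along Z through the center."""
    data = np.zeros((9, 9, 9), dtype=np.float32)
    data[:, 4, 4] = 1.0
    return Volume(data)


@pytest.fixture(scope="session")
def small_phantom():
    """64^3 phantom with 3 well-separated fibers and ground truth."""
    spec = PhantomSpec(volume_size=64, n_fibers=3, radius_range=(3, 5), gap_range=(3, 5), seed=1)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def coarse_grid() -> AngularGrid:
    """5-degree scan grid to keep unit tests fast."""
    return AngularGrid(azimuth_step=5.0, elevation_step=5.0)


def rasterize_cylinder(size: int, orientation: Orientation, radius: float) -> Volume:
    """Solid straight cylinder through the cube center at the given angles."""
    from fibray import direction_vector

    d = direction_vector(orientation)  # (x, y, z)
    u = np.array([d[2], d[1], d[0]])
    c = (size - 1) / 2.0
    zz, yy, xx = np.indices((size, size, size), dtype=np.float64)
    rel = np.stack([zz - c, yy - c, xx - c], axis=-1)
    t = rel @ u
    d2 = (rel**2).sum(axis=-1) - t**2
    return Volume((d2 <= radius**2).astype(np.float32))


def rasterize_line(size: int, orientation: Orientation) -> Volume:
    """Single-voxel-wide straight line through the cube center."""
    from fibray import direction_vector

    d = direction_vector(orientation)  # (x, y, z)
    c = (size - 1) / 2.0
    data = np.zeros((size, size, size), dtype=np.float32)
    for t in np.arange(-size, size, 0.25):
        x = int(np.floor(c + t * d[0] + 0.5))
        y = int(np.floor(c + t * d[1] + 0.5))
        z = int(np.floor(c + t * d[2] + 0.5))
        if 0 <= x < size and 0 <= y < size and 0 <= z < size:
            data[z, y, x] = 1.0
    return Volume(data)
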