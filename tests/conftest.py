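import numpy as np
import pytest

from zotrad import VoxelMask, ccrcc_like_spec, ro_like_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sphere_mask():
    """Digital sphere of radius 10 voxels centered in a 32^3 grid."""
    zz, yy, xx = np.ogrid[:32, :32, :32]
    c = 15.5
    grid = (xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2 <= 10.0**2
    return VoxelMask(grid)


@pytest.fixture
def phantom_pair():
    """One zero-noise RO-like and one ccRCC-like phantom spec pair."""
    return (
        ro_like_spec(noise_sd=0.0, grid_shape=(40, 40, 40)),
        ccrcc_like_spec(noise_sd=0.0, grid_shape=(40, 40, 40)),
    )


def minkowski_dilate(grid: np.ndarray, element: np.ndarray) -> np.ndarray:
    """Brute-force dilation: OR of the mask shifted by every element offset."""
    r = element.shape[0] // 2
    out = np.zeros_like(grid)
    for dz in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                if not element[dz + r, dy + r, dx + r]:
                    continue
                out |= shift_mask(grid, (dz, dy, dx))
    return out


def minkowski_erode(grid: np.ndarray, element: np.ndarray) -> np.ndarray:
    """Brute-force erosion: AND of shifts, out-of-grid treated as background."""
    r = element.shape[0] // 2
    out = np.ones_like(grid)
    for dz in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                if not element[dz + r, dy + r, dx + r]:
                    continue
                out &= shift_mask(grid, (-dz, -dy, -dx))
    return out


def shift_mask(grid: np.ndarray, offset) -> np.ndarray:
    """Shift a boolean grid, filling with False (background)."""
    out = np.zeros_like(grid)
    src = []
    dst = []
    for o, n in zip(offset, grid.shape):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    out[tuple(dst)] = grid[tuple(src)]
    return out


def zot_oracle(grid: np.ndarray, element: np.ndarray, iterations: int = 2):
    """Independent ZOT oracle via repeated Minkowski sums/differences."""
    d = grid.copy()
    e = grid.copy()
    for _ in range(iterations):
        d = minkowski_dilate(d, element)
        e = minkowski_erode(e, element)
    return d & ~e, d, e
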