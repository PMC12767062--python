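import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def sierpinski_carpet(depth: int = 4, upscale: int = 3) -> np.ndarray:
    """Rasterized Sierpinski carpet; ``upscale`` px per finest-level cell so
    the smallest counting boxes resolve the finest holes."""
    m = np.ones((1, 1), dtype=bool)
    for _ in range(depth):
        z = np.zeros_like(m)
        m = np.block([[m, m, m], [m, z, m], [m, m, m]])
    return np.kron(m, np.ones((upscale, upscale), dtype=bool))


def brute_force_msd(positions: np.ndarray, frames: np.ndarray, dt: float):
    """O(n²) double-loop MSD oracle: all ordered pairs grouped by frame lag."""
    sums: dict[int, list[float]] = {}
    n = len(positions)
    for i in range(n):
        for j in range(i + 1, n):
            lag = int(frames[j] - frames[i])
            d = positions[j] - positions[i]
            sums.setdefault(lag, []).append(float(d @ d))
    lags = sorted(sums)
    return (np.array([lag * dt for lag in lags]),
            np.array([np.mean(sums[lag]) for lag in lags]),
            np.array([len(sums[lag]) for lag in lags]))
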