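"""Shared numerical helpers: Gaussian smoothing, run finding, seed streams."""

from __future__ import annotations

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng

# Fixed stream keys so that e.g. adding a unit never perturbs the trajectory
# stream or the streams of other units.
STREAM_TASK = 1
STREAM_TRAJECTORY = 2
STREAM_UNIT = 3
STREAM_SHUFFLE = 4
STREAM_SHIFT = 5

#: Gaussian kernels are truncated at +/- 4 standard deviations.
KERNEL_TRUNCATE_SD = 4.0


def stream_rng(master_seed: int, *key: int) -> Generator:
    """Independent random stream derived from the master seed and a fixed key."""
    return default_rng(SeedSequence(master_seed, spawn_key=tuple(key)))


def gaussian_kernel(sd_samples: float) -> np.ndarray:
    """Discrete Gaussian kernel truncated at ±4 sd and renormalized to unit sum."""
    if sd_samples <= 0:
        raise ValueError(f"kernel sd must be positive, got {sd_samples}")
    half = int(np.ceil(KERNEL_TRUNCATE_SD * sd_samples))
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sd_samples) ** 2)
    return k / k.sum()


def gaussian_smooth(x: np.ndarray, sd_samples: float, axis: int = -1) -> np.ndarray:
    """Convolve with a unit-sum truncated Gaussian, edge values extended.

    Edge extension (rather than zero padding) keeps constants invariant all
    the way to the array ends and matches the nearest-interval extension used
    for firing rates.
    """
    from scipy.ndimage import convolve1d

    k = gaussian_kernel(sd_samples)
    return convolve1d(np.asarray(x, dtype=float), k, axis=axis, mode="nearest")


def contiguous_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs in a boolean vector."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        return []
    edges = np.diff(flags.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    stops = list(np.nonzero(edges == -1)[0] + 1)
    if flags[0]:
        starts.insert(0, 0)
    if flags[-1]:
        stops.append(flags.size)
    return list(zip(starts, stops))
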