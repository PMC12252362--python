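"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from flfaquant import DetectorConfig, WaveletParams
from flfaquant.simulate import Band, Background, SceneSpec, generate


# ---------------------------------------------------------------------------
# independent naive CWT oracle: direct formula sampling, explicit padding,
# explicit per-sample dot products — no shared code with flfaquant.wavelet
# ---------------------------------------------------------------------------

def naive_kernel(sigma: float, support_len: int) -> np.ndarray:
    length = support_len + 1 if support_len % 2 == 0 else support_len
    half = length // 2
    t = np.arange(-half, half + 1, dtype=float)
    return (1.0 - (t / sigma) ** 2) * np.exp(-(t**2) / (2.0 * sigma**2))


def naive_extend(x: np.ndarray, half: int) -> np.ndarray:
    nfit = min(x.size, 2 * half + 1)
    idx = np.arange(nfit, dtype=float)
    bl, al = np.polyfit(idx, x[:nfit], 1)  # slope, intercept
    br, ar = np.polyfit(idx, x[-nfit:], 1)
    left = al + bl * np.arange(-half, 0, dtype=float)
    right = ar + br * (np.arange(1, half + 1, dtype=float) + nfit - 1)
    return np.concatenate([left, x, right])


def naive_cwt(x: np.ndarray, params: WaveletParams) -> np.ndarray:
    """Aggregated detection curve by brute-force direct convolution."""
    x = np.asarray(x, dtype=float)
    rows = []
    for s in params.scales:
        k = naive_kernel(s, params.support_len)
        k = (k - k.mean()) / np.sqrt(s)
        half = k.size // 2
        padded = naive_extend(x, half)
        out = np.empty(x.size)
        for tau in range(x.size):
            # convolution: flip the kernel (symmetric here, but be literal)
            out[tau] = float(np.dot(padded[tau : tau + k.size], k[::-1]))
        rows.append(out)
    if params.aggregate == "mean":
        return np.mean(rows, axis=0)
    if params.aggregate == "single_scale":
        return rows[0]
    return np.max(rows, axis=0)


def tent_curve(length, apex, j_left, j_right, depth=10.0, height=20.0):
    """Piecewise-linear curve with local minima exactly at j_left/j_right
    and a local maximum at apex.

    The slope magnitude is matched on both sides of each trough kink, so
    the interval derivative is exactly zero there and the detector's
    trough indices are unambiguous.
    """
    x = np.arange(length, dtype=float)
    sl = height / (apex - j_left)
    sr = height / (j_right - apex)
    curve = np.where(
        x <= j_left,
        depth + sl * (j_left - x),
        np.where(
            x <= apex,
            depth + sl * (x - j_left),
            np.where(x <= j_right, depth + sr * (j_right - x), depth + sr * (x - j_right)),
        ),
    )
    return curve


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def wparams() -> WaveletParams:
    return WaveletParams()


@pytest.fixture(scope="session")
def dconfig() -> DetectorConfig:
    return DetectorConfig()


@pytest.fixture(scope="session")
def band_image():
    """Noise-free flat-background single-band strip image + ground truth."""
    spec = SceneSpec(
        shape=(200, 600),
        background=Background(base=40.0),
        bands=(Band(center=300, sigma=22.0, amplitude=50.0),),
        noise_sigma=0.0,
        seed=11,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def two_band_image():
    """Noise-free strip with two bands at known centers."""
    spec = SceneSpec(
        shape=(200, 600),
        background=Background(base=40.0),
        bands=(
            Band(center=190, sigma=20.0, amplitude=40.0),
            Band(center=430, sigma=20.0, amplitude=60.0),
        ),
        noise_sigma=0.0,
        seed=12,
    )
    return generate(spec)
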