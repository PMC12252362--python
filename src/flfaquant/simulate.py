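"""Synthetic strip and dot-matrix image generator with ground truth.

Emulates the filter-free imaging regime: a dark-but-elevated background
with a smooth stray-light gradient, one to three weak transverse
fluorescent bands (strip format) or a grid of 2-D Gaussian spots
(dot-matrix format), additive Gaussian sensor read noise, and optional
salt impulses (hot pixels).  Amplitudes can be driven down to
near-invisible contrast, which is the regime the detection pipeline
exists for.

Every image is reproducible from its :class:`SceneSpec` (including the
seed) and is delivered together with a :class:`GroundTruth` carrying the
true geometry and the closed-form expected avePix from
:mod:`flfaquant.analytic`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

from .analytic import band_avepix, spot_avepix
from .errors import ConfigError
from .image_io import ImageMatrix
from .wavelet import WaveletParams


@dataclass(frozen=True)
class Background:
    """Stray-light model: base level plus linear/quadratic gradients,
    parameterized about the image center (gray values per px, per px^2)."""

    base: float = 40.0
    slope_x: float = 0.0
    slope_y: float = 0.0
    quad_x: float = 0.0
    quad_y: float = 0.0


@dataclass(frozen=True)
class Band:
    """Transverse fluorescent line (strip format).

    Cross-section along X is Gaussian by default; a nonzero
    ``flat_width`` makes it flat-topped (box of that half-width convolved
    with the Gaussian).  ``row_top``/``row_bottom`` default to the full
    strip height, as capture lines cross the whole imaged window.
    """

    center: float
    sigma: float
    amplitude: float
    row_top: int | None = None
    row_bottom: int | None = None
    flat_width: float = 0.0


@dataclass(frozen=True)
class Spot:
    """Isotropic 2-D Gaussian spot (dot-matrix format)."""

    row: float
    col: float
    sigma: float
    amplitude: float


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic scene."""

    shape: tuple[int, int] = (200, 600)
    background: Background = field(default_factory=Background)
    bands: tuple[Band, ...] = ()
    spots: tuple[Spot, ...] = ()
    noise_sigma: float = 2.0
    impulse_fraction: float = 0.0
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.shape
        if h < 1 or w < 1:
            raise ConfigError(f"invalid shape {self.shape}")
        if self.bit_depth not in (8, 16):
            raise ConfigError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if not 0 <= self.impulse_fraction <= 1:
            raise ConfigError("impulse_fraction must be in [0, 1]")
        for b in self.bands:
            if b.amplitude < 0 or b.sigma <= 0:
                raise ConfigError("band amplitude must be >= 0 and sigma > 0")
            if not 0 <= b.center < w:
                raise ConfigError(f"band center {b.center} outside image of width {w}")
        for s in self.spots:
            if s.amplitude < 0 or s.sigma <= 0:
                raise ConfigError("spot amplitude must be >= 0 and sigma > 0")
            if not (0 <= s.row < h and 0 <= s.col < w):
                raise ConfigError("spot center outside image")

    @property
    def max_gray(self) -> int:
        return 255 if self.bit_depth == 8 else 65535


@dataclass(frozen=True)
class BandTruth:
    center: float
    sigma: float
    amplitude: float
    x_left: int  # center - 3 sigma, rounded
    x_right: int
    integrated_signal: float  # background-subtracted mass per scan line
    analytic_avepix: float | None


@dataclass(frozen=True)
class SpotTruth:
    row: float
    col: float
    sigma: float
    amplitude: float
    integrated_signal: float
    analytic_avepix: float | None


@dataclass(frozen=True)
class GroundTruth:
    bands: tuple[BandTruth, ...]
    spots: tuple[SpotTruth, ...]
    saturated: bool
    spec: SceneSpec


def _band_profile(band: Band, x: np.ndarray) -> np.ndarray:
    t = x - band.center
    if band.flat_width <= 0:
        return band.amplitude * np.exp(-0.5 * (t / band.sigma) ** 2)
    # box (+-flat_width) convolved with the Gaussian, unit peak at center
    sq2 = band.sigma * np.sqrt(2.0)
    prof = 0.5 * (erf((t + band.flat_width) / sq2) - erf((t - band.flat_width) / sq2))
    return band.amplitude * prof / erf(band.flat_width / sq2)


def scene_values(spec: SceneSpec) -> np.ndarray:
    """Pre-noise, pre-quantization scene (background + signal profiles).

    Signals superpose additively over the single background, so
    scene(A + B) = scene(A) + scene(B) - background.
    """
    h, w = spec.shape
    y = np.arange(h, dtype=np.float64)[:, None] - (h - 1) / 2.0
    x = np.arange(w, dtype=np.float64)[None, :] - (w - 1) / 2.0
    bg = spec.background
    scene = (
        bg.base
        + bg.slope_x * x
        + bg.slope_y * y
        + bg.quad_x * x * x
        + bg.quad_y * y * y
    ) * np.ones((h, w))
    cols = np.arange(w, dtype=np.float64)
    rows = np.arange(h, dtype=np.float64)
    for band in spec.bands:
        profile = _band_profile(band, cols)
        top = 0 if band.row_top is None else band.row_top
        bottom = h - 1 if band.row_bottom is None else band.row_bottom
        scene[top : bottom + 1, :] += profile[None, :]
    for spot in spec.spots:
        gy = np.exp(-0.5 * ((rows - spot.row) / spot.sigma) ** 2)
        gx = np.exp(-0.5 * ((cols - spot.col) / spot.sigma) ** 2)
        scene += spot.amplitude * gy[:, None] * gx[None, :]
    return scene


def _ground_truth(spec: SceneSpec, scene: np.ndarray, params: WaveletParams) -> GroundTruth:
    bands = []
    for b in spec.bands:
        avepix = band_avepix(b.amplitude, b.sigma, params) if b.flat_width <= 0 else None
        bands.append(
            BandTruth(
                center=b.center,
                sigma=b.sigma,
                amplitude=b.amplitude,
                x_left=int(round(b.center - 3 * b.sigma)),
                x_right=int(round(b.center + 3 * b.sigma)),
                integrated_signal=float(b.amplitude * b.sigma * np.sqrt(2 * np.pi)),
                analytic_avepix=avepix,
            )
        )
    spots = [
        SpotTruth(
            row=s.row,
            col=s.col,
            sigma=s.sigma,
            amplitude=s.amplitude,
            integrated_signal=float(s.amplitude * 2 * np.pi * s.sigma**2),
            analytic_avepix=spot_avepix(s.amplitude, s.sigma, params),
        )
        for s in spec.spots
    ]
    return GroundTruth(
        bands=tuple(bands),
        spots=tuple(spots),
        saturated=bool(scene.max() > spec.max_gray),
        spec=spec,
    )


def generate(
    spec: SceneSpec, params: WaveletParams = WaveletParams()
) -> tuple[ImageMatrix, GroundTruth]:
    """Render a scene: add noise, clip to range, quantize to bit depth.

    Deterministic for a given spec (the seed is part of it).  A scene
    whose noise-free values exceed full scale is flagged ``saturated`` in
    the ground truth, not rejected.  ``params`` only parameterizes the
    analytic avePix the ground truth carries.
    """
    scene = scene_values(spec)
    rng = np.random.default_rng(spec.seed)
    img = scene.copy()
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    if spec.impulse_fraction > 0:
        mask = rng.random(img.shape) < spec.impulse_fraction
        img[mask] = spec.max_gray
    img = np.clip(np.rint(img), 0, spec.max_gray)
    matrix = ImageMatrix(img, spec.max_gray, "gray")
    return matrix, _ground_truth(spec, scene, params)


def weak_signal_suite(
    n_scenes: int,
    snr_range: tuple[float, float] = (2.0, 4.0),
    seed: int = 0,
    replicates: int = 5,
    *,
    noise_sigma: float = 2.0,
    impulse_fraction: float = 0.0,
    shape: tuple[int, int] = (200, 600),
    n_bands: tuple[int, ...] = (1, 2, 3),
    sigma_range: tuple[float, float] = (18.0, 26.0),
    min_separation: int = 150,
    margin: int = 90,
) -> list[tuple[ImageMatrix, GroundTruth]]:
    """Seeded suite of low-contrast strip scenes with ground truth.

    Each of ``n_scenes`` scene configurations draws its geometry once
    (band count, integer centers separated by at least
    ``min_separation`` px, band width, background level and gradients)
    and its band amplitudes as ``U(snr_range) * noise_sigma`` — i.e. the
    peak contrast over the background noise sigma lies in ``snr_range``.
    Each configuration is rendered ``replicates`` times with distinct
    noise seeds, giving ``n_scenes * replicates`` images, all
    reproducible from ``seed``.
    """
    if n_scenes < 1 or replicates < 1:
        raise ConfigError("n_scenes and replicates must be >= 1")
    lo, hi = snr_range
    if lo <= 0 or hi < lo:
        raise ConfigError(
            f"snr_range must satisfy 0 < low <= high, got {snr_range}"
        )
    h, w = shape
    rng = np.random.default_rng(seed)
    suite: list[tuple[ImageMatrix, GroundTruth]] = []
    for _ in range(n_scenes):
        k = int(rng.choice(n_bands))
        span = (w - 2 * margin) - (k - 1) * min_separation
        if span <= 0:
            raise ConfigError(
                f"cannot place {k} bands {min_separation} px apart within width {w}"
            )
        offsets = np.sort(rng.uniform(0, span, size=k))
        centers = [
            int(round(margin + off + i * min_separation))
            for i, off in enumerate(offsets)
        ]
        sigma_b = float(rng.uniform(*sigma_range))
        background = Background(
            base=float(rng.uniform(30, 60)),
            slope_x=float(rng.uniform(-1, 1) * 8.0 / w),
            slope_y=float(rng.uniform(-1, 1) * 5.0 / h),
        )
        bands = tuple(
            Band(center=c, sigma=sigma_b, amplitude=float(rng.uniform(lo, hi) * noise_sigma))
            for c in centers
        )
        for _ in range(replicates):
            spec = SceneSpec(
                shape=shape,
                background=background,
                bands=bands,
                noise_sigma=noise_sigma,
                impulse_fraction=impulse_fraction,
                seed=int(rng.integers(2**31)),
            )
            suite.append(generate(spec))
    return suite
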