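"""Closed-form noise-free theory of the detection pipeline.

For a Gaussian signal cross-section p(t) = a * exp(-t^2 / (2 sigma_b^2)),
every stage of the noise-free pipeline has a closed form:

* the response of a truncated, mean-corrected Mexican Hat kernel to p is
  an erf/exp expression (Gaussian-times-Gaussian integrals reduce to
  truncated-normal moments, and the Mexican Hat integrates exactly since
  d/dv [v exp(-v^2/2s^2)] = psi_s(v));
* the detector's trough positions are the stationary points of that
  response;
* avePix over the trough window is a Gaussian integral minus the window
  baseline.

Two regimes are modeled.  Positioning runs on a long projection curve, so
the band sees the full kernel over an effectively infinite profile.  Scan
lines, however, are restricted to the extracted region: the profile is
only one trough-window long, the kernel shrinks to match, and beyond the
region the curve is continued at the fitted-line level (the mean of the
windowed profile, by symmetry).  Both regimes are pure formula evaluation
plus a 1-D minimization — they never touch the wavelet or peak code, and
serve as the independent ground truth that synthetic scenes carry.

All lengths are in samples (pixels); responses are per unit amplitude
unless an amplitude is given.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import erf, ndtr  # ndtr = standard normal CDF

from .errors import ConfigError
from .wavelet import WaveletParams

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _phi(z):
    return np.exp(-0.5 * np.asarray(z) ** 2) / _SQRT2PI


def _psi_int(s: float, lo, hi):
    """Integral of the Mexican Hat psi_s over [lo, hi] (exact)."""
    lo, hi = np.asarray(lo, float), np.asarray(hi, float)
    return hi * np.exp(-0.5 * (hi / s) ** 2) - lo * np.exp(-0.5 * (lo / s) ** 2)


def _gauss_int(tau, sigma_b: float, lo, hi):
    """Integral over v in [lo, hi] of exp(-(tau - v)^2 / 2 sigma_b^2)."""
    tau = np.asarray(tau, float)
    return sigma_b * _SQRT2PI * (ndtr((hi - tau) / sigma_b) - ndtr((lo - tau) / sigma_b))


def _psi_gauss_int(tau, s: float, sigma_b: float, lo, hi):
    """Integral over v in [lo, hi] of psi_s(v) * exp(-(tau-v)^2/2 sigma_b^2).

    The exponential product is a Gaussian in v of width sp about mu, so
    the polynomial factor reduces to truncated-normal moments.
    """
    tau = np.asarray(tau, float)
    se2 = s * s + sigma_b * sigma_b
    sp = s * sigma_b / np.sqrt(se2)
    mu = tau * s * s / se2
    z1 = (lo - mu) / sp
    z2 = (hi - mu) / sp
    phi1, phi2 = _phi(z1), _phi(z2)
    m0 = ndtr(z2) - ndtr(z1)
    m2 = (mu * mu + sp * sp) * m0 + 2 * mu * sp * (phi1 - phi2) + sp * sp * (
        z1 * phi1 - z2 * phi2
    )
    return np.exp(-0.5 * tau * tau / se2) * sp * _SQRT2PI * (m0 - m2 / (s * s))


def _check_mean_aggregate(params: WaveletParams) -> tuple[float, ...]:
    if params.aggregate == "max":
        raise ConfigError(
            "closed-form response is defined for mean/single_scale aggregation"
        )
    return params.scales[:1] if params.aggregate == "single_scale" else params.scales


def band_response(
    tau, amplitude: float, sigma_b: float, params: WaveletParams = WaveletParams()
) -> np.ndarray:
    """Noise-free combined detection curve at offsets tau from a Gaussian
    band center, positioning regime (long curve, full kernel support)."""
    half = params.kernel_len // 2
    rows = []
    for s in _check_mean_aggregate(params):
        m_s = _psi_int(s, -half, half) / (2 * half + 1)
        resp = _psi_gauss_int(tau, s, sigma_b, -half, half) - m_s * _gauss_int(
            tau, sigma_b, -half, half
        )
        rows.append(amplitude * resp / np.sqrt(s))
    return np.mean(rows, axis=0)


def _row_response(tau, sigma_b: float, half_row: float, params: WaveletParams):
    """Per-unit-amplitude detection curve of one scan line.

    The profile exists on [-half_row, half_row] and is continued outside
    at its own window mean (the fitted-line extension level; the slope is
    zero by symmetry); the kernel half-width equals half_row, as the
    region length forces the adapted support.
    """
    tau = np.asarray(tau, float)
    hk = hr = float(half_row)
    g_mean = sigma_b * _SQRT2PI * erf(hr / (sigma_b * np.sqrt(2.0))) / (2 * hr + 1)
    rows = []
    for s in _check_mean_aggregate(params):
        m_s = _psi_int(s, -hk, hk) / (2 * hk + 1)
        glo = np.maximum(-hk, tau - hr)
        ghi = np.minimum(hk, tau + hr)
        width = np.maximum(ghi - glo, 0.0)
        inside_psi = np.where(width > 0, _psi_gauss_int(tau, s, sigma_b, glo, ghi), 0.0)
        inside_g = np.where(width > 0, _gauss_int(tau, sigma_b, glo, ghi), 0.0)
        outside_psi = _psi_int(s, -hk, hk) - np.where(
            width > 0, _psi_int(s, glo, ghi), 0.0
        )
        resp = (
            inside_psi
            + g_mean * outside_psi
            - m_s * (inside_g + g_mean * (2 * hk - width))
        )
        rows.append(resp / np.sqrt(s))
    return np.mean(rows, axis=0)


def trough_offset(sigma_b: float, params: WaveletParams = WaveletParams()) -> float:
    """Distance T from a Gaussian band's center to the positioning-stage
    trough (minimum of the noise-free detection curve); independent of
    amplitude by linearity."""
    hi = 3.0 * np.sqrt(max(params.scales) ** 2 + sigma_b**2)
    res = minimize_scalar(
        lambda t: band_response(t, 1.0, sigma_b, params),
        bounds=(1.0, hi),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return float(res.x)


def row_window(sigma_b: float, params: WaveletParams = WaveletParams()) -> float:
    """Half-width T of the per-scan-line integration window.

    Positioning finds the region troughs at +-T_x; each scan line is then
    re-analyzed on the profile restricted to that region (shrunken
    kernel, fitted-level continuation), giving its own trough offset —
    clamped to the region bound, since the region ends serve as fallback
    troughs.
    """
    t_x = trough_offset(sigma_b, params)
    half_row = float(round(t_x))
    row_params = params.adapted(2 * int(half_row) + 1)
    if max(row_params.scales) < min(params.scales):
        # scales collapsed to the half-support; keep the formula honest
        half_row = min(half_row, float(row_params.kernel_len // 2))
    res = minimize_scalar(
        lambda t: _row_response(t, sigma_b, half_row, row_params),
        bounds=(1.0, half_row),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return float(min(res.x, t_x))


def band_avepix(
    amplitude: float, sigma_b: float, params: WaveletParams = WaveletParams()
) -> float:
    """Analytic avePix of a noise-free full-height Gaussian band.

    The scan-line window is [-T, T] with T from :func:`row_window`; the
    baseline is the profile value at the troughs; the numerator sums
    2 T + 1 pixel columns and the denominator counts a width of 2 T,
    mirroring the discrete statistic.
    """
    t = row_window(sigma_b, params)
    base = amplitude * np.exp(-0.5 * t * t / (sigma_b * sigma_b))
    integral = amplitude * sigma_b * _SQRT2PI * erf(t / (sigma_b * np.sqrt(2.0)))
    return float((integral - (2 * t + 1) * base) / (2 * t))


def spot_avepix(
    amplitude: float,
    sigma_spot: float,
    params: WaveletParams = WaveletParams(),
    quant_step: float = 1.0,
) -> float:
    """Analytic avePix of a noise-free 2-D Gaussian spot (approximate).

    Scan lines within the Y trough window carry a Gaussian amplitude
    profile; each line is quantified like a band of the same width, and
    the per-line numerators/widths aggregate in closed form.  Lines whose
    peak amplitude falls below half the gray-level quantization step
    round flat and detect nothing, so they are excluded (they carry
    almost no mass but would otherwise inflate the width sum).
    """
    t = row_window(sigma_spot, params)
    t_y = trough_offset(sigma_spot, params)
    sq2 = sigma_spot * np.sqrt(2.0)
    base = np.exp(-0.5 * t * t / (sigma_spot * sigma_spot))
    per_unit_num = sigma_spot * _SQRT2PI * erf(t / sq2) - (2 * t + 1) * base
    if amplitude > quant_step:
        y_max = sigma_spot * np.sqrt(2.0 * np.log(2.0 * amplitude / quant_step))
    else:
        y_max = 0.0
    y_max = min(y_max, t_y)
    row_amp_sum = amplitude * sigma_spot * _SQRT2PI * erf(y_max / sq2)
    n_rows = 2 * y_max + 1
    return float(per_unit_num * row_amp_sum / (n_rows * 2 * t))
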