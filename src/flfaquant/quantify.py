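"""ROI extraction and per-scanline quantification.

Stage 1 (positioning) projects the image along X (one value per column),
runs the wavelet peak pipeline, and turns each accepted peak's trough span
into a column slab.  Within each slab the Y projection is analyzed the
same way: no accepted peak means the slab holds uniform strip fluorescence
(one full-height ROI); accepted peaks segment the slab into one spot ROI
each (dot-matrix format).

Stage 2 (quantification) scans each ROI row by row.  Every scan line is
pushed through the same wavelet peak pipeline; when a line yields an
accepted peak, its trough columns dp_l(y), dp_r(y) bound the signal, the
baseline is the mean of the raw row values at those columns, and the
background-subtracted area between them is accumulated.  The statistic

    avePix = sum_y sum_{x = dp_l(y)}^{dp_r(y)} (f(x, y) - baseval_y)
             / sum_y (dp_r(y) - dp_l(y))

averages the fluorescence per pixel over the detected scan lines.  Lines
with no accepted peak contribute to neither sum: at weak signal levels,
folding undetected lines in at ROI-wide bounds would dilute exactly the
signals the method exists to preserve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ProcessingError
from .image_io import ImageMatrix
from .peaks import DetectorConfig, Peak, accept_peak, find_peaks
from .projection import COLLAPSE_COLS, COLLAPSE_ROWS, project
from .wavelet import WaveletParams, cwt, estimate_noise_sigma

logger = logging.getLogger(__name__)

MODES = ("auto", "strip", "dot")
#: narrowest profile the wavelet pipeline will analyze
MIN_CURVE_LEN = 9


@dataclass(frozen=True)
class ROI:
    """Inclusive fluorescence region bounds.

    ``mode`` is "strip" (full-height band) or "spot" (Y-segmented).
    ``apex_x``/``apex_y`` record the projection-peak apex positions.
    """

    x_left: int
    x_right: int
    top: int
    down: int
    mode: str
    apex_x: int
    apex_y: int | None = None


@dataclass(frozen=True)
class RowScan:
    """One scan line of a quantified ROI (absolute image coordinates)."""

    y: int
    dp_l: int
    dp_r: int
    baseval: float
    area: float
    detected: bool


@dataclass(frozen=True)
class QuantResult:
    """Quantification of one ROI.

    avepix : mean background-subtracted gray value per pixel over the
        detected scan lines (0 when no line detects a peak)
    volume : total background-subtracted signal (sum of row areas)
    surface : background-subtracted value grid of the ROI (values below
        the row baseline clipped to 0, zeros outside the row bounds),
        for 3-D reconstruction
    """

    roi: ROI
    rows: tuple[RowScan, ...]
    avepix: float
    volume: float
    surface: np.ndarray = field(repr=False, default=None)


def curve_peaks(
    values: np.ndarray,
    wavelet_params: WaveletParams,
    det_config: DetectorConfig,
) -> tuple[list[Peak], list[Peak]]:
    """Run the transform + peak pipeline on one raw profile.

    Returns (accepted, all) peaks.  Trough positions come from the
    detection (combined wavelet) curve; baseline values are read from the
    raw profile.  Wavelet support/scales shrink automatically for
    profiles shorter than the configured support.
    """
    values = np.asarray(getattr(values, "values", values), dtype=np.float64)
    params = wavelet_params.adapted(values.size)
    result = cwt(values, params)
    noise_level = estimate_noise_sigma(values) * result.noise_gain
    peaks = find_peaks(result.combined, values, det_config, noise_level)
    # Near the curve ends the kernel hangs over synthesized (extrapolated)
    # samples, so apexes there are boundary artifacts, not signals; only
    # apexes where the kernel mostly overlaps real data are accepted.
    margin = min(params.kernel_len // 2, values.size // 4)
    accepted = [
        p
        for p in peaks
        if accept_peak(p, det_config) and margin <= p.apex <= values.size - 1 - margin
    ]
    return accepted, peaks


def locate_bands(
    image: ImageMatrix,
    wavelet_params: WaveletParams = WaveletParams(),
    det_config: DetectorConfig = DetectorConfig(),
) -> list[Peak]:
    """Accepted peaks of the X-direction (per-column) projection curve."""
    xcurve = project(image, COLLAPSE_ROWS)
    accepted, all_peaks = curve_peaks(xcurve.values, wavelet_params, det_config)
    logger.debug(
        "X projection: %d candidate peaks, %d accepted (rejected: %s)",
        len(all_peaks),
        len(accepted),
        [
            f"apex={p.apex} sep={p.j_right - p.j_left} snr={p.snr:.1f}"
            for p in all_peaks
            if p not in accepted
        ],
    )
    return accepted


def extract_rois(
    image: ImageMatrix,
    wavelet_params: WaveletParams = WaveletParams(),
    det_config: DetectorConfig = DetectorConfig(),
    mode: str = "auto",
) -> list[ROI]:
    """X-then-Y projection positioning.

    mode "strip" skips the Y segmentation step (every slab becomes one
    full-height ROI); "auto"/"dot" segment a slab whenever its Y
    projection yields accepted peaks, and fall back to a full-height
    strip ROI otherwise.
    """
    if mode not in MODES:
        raise ProcessingError(f"mode must be one of {MODES}, got {mode!r}")
    rois: list[ROI] = []
    for xpeak in locate_bands(image, wavelet_params, det_config):
        x_left, x_right, apex_x = xpeak.j_left, xpeak.j_right, xpeak.apex
        if mode != "strip" and image.h >= MIN_CURVE_LEN:
            ycurve = project(image, COLLAPSE_COLS, (0, image.h - 1, x_left, x_right))
            ypeaks, _ = curve_peaks(ycurve.values, wavelet_params, det_config)
        else:
            ypeaks = []
        if not ypeaks:
            rois.append(ROI(x_left, x_right, 0, image.h - 1, "strip", apex_x))
        else:
            logger.debug(
                "slab [%d, %d]: %d Y peaks -> spot segmentation", x_left, x_right, len(ypeaks)
            )
            for yp in ypeaks:
                rois.append(
                    ROI(x_left, x_right, yp.j_left, yp.j_right, "spot", apex_x, yp.apex)
                )
    return rois


def _best_peak(peaks: list[Peak]) -> Peak:
    return max(peaks, key=lambda p: p.prominence)


def row_integral(
    profile: np.ndarray, dp_l: int, dp_r: int, baseval: float
) -> tuple[float, int]:
    """Background-subtracted area and width of one scan line.

    The area sums the inclusive pixel range [dp_l, dp_r] minus the
    baseline; the width counts dp_r - dp_l, exactly as the avePix
    denominator does.  Indices are relative to ``profile``.
    """
    area = float(np.sum(profile[dp_l : dp_r + 1] - baseval))
    return area, dp_r - dp_l


def quantify_roi(
    image: ImageMatrix,
    roi: ROI,
    wavelet_params: WaveletParams = WaveletParams(),
    det_config: DetectorConfig = DetectorConfig(),
) -> QuantResult:
    """Scan an ROI line by line and aggregate avePix.

    Raises on a degenerate ROI too narrow for wavelet analysis.
    """
    width = roi.x_right - roi.x_left + 1
    if width < MIN_CURVE_LEN:
        raise ProcessingError(
            f"degenerate ROI: width {width} px is too narrow to quantify "
            f"(minimum {MIN_CURVE_LEN})"
        )
    rows: list[RowScan] = []
    volume = 0.0
    width_sum = 0
    surface = np.zeros((roi.down - roi.top + 1, width))
    for y in range(roi.top, roi.down + 1):
        profile = image.data[y, roi.x_left : roi.x_right + 1]
        accepted, _ = curve_peaks(profile, wavelet_params, det_config)
        if not accepted:
            rows.append(RowScan(y, roi.x_left, roi.x_right, 0.0, 0.0, False))
            continue
        peak = _best_peak(accepted)
        dp_l = roi.x_left + peak.j_left
        dp_r = roi.x_left + peak.j_right
        baseval = peak.baseval  # mean of the raw row values at the troughs
        area, width = row_integral(profile, peak.j_left, peak.j_right, baseval)
        segment = image.data[y, dp_l : dp_r + 1]
        rows.append(RowScan(y, dp_l, dp_r, baseval, area, True))
        volume += area
        width_sum += width
        surface[y - roi.top, peak.j_left : peak.j_right + 1] = np.maximum(
            segment - baseval, 0.0
        )
    avepix = volume / width_sum if width_sum > 0 else 0.0
    if width_sum == 0:
        volume = 0.0
    return QuantResult(roi, tuple(rows), float(avepix), float(volume), surface)


def quantify_image(
    image: ImageMatrix,
    wavelet_params: WaveletParams = WaveletParams(),
    det_config: DetectorConfig = DetectorConfig(),
    mode: str = "auto",
) -> list[QuantResult]:
    """Full pipeline on one image: extract ROIs, quantify each."""
    return [
        quantify_roi(image, roi, wavelet_params, det_config)
        for roi in extract_rois(image, wavelet_params, det_config, mode)
    ]
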