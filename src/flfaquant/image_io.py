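"""Image input/output: load strip photos, write quantification reports.

The working representation is :class:`ImageMatrix`, a float64 intensity
matrix at the native bit-depth scale (values in ``[0, max_gray]``).  Color
images are reduced to a single plane on load; the default policy keeps the
red channel, because quantum-dot labels emit red fluorescence on a dark
stray-light background, so the red plane carries the highest contrast.

Row 0 is the top of the image.  The "X direction" is the column index (the
long axis of the strip, crossing the T/C lines); the "Y direction" is the
row index.  All ROI bounds are inclusive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

from .errors import ConfigError, ImageIOError

if TYPE_CHECKING:  # pragma: no cover
    from .quantify import QuantResult

#: BT.601 luminance weights for the ``luminance`` channel policy.
LUMINANCE_WEIGHTS = (0.299, 0.587, 0.114)

CHANNEL_POLICIES = ("red", "luminance", "gray")


@dataclass(frozen=True)
class ImageMatrix:
    """2-D intensity matrix extracted from a strip photo.

    Parameters
    ----------
    data : ndarray, shape (h, w)
        Pixel intensities, finite, in ``[0, max_gray]``.
    max_gray : int
        Full-scale value of the source bit depth (255 or 65535).
    channel_policy : str
        How color was reduced ("red", "luminance", or "gray" for
        single-channel sources).
    """

    data: np.ndarray
    max_gray: int = 255
    channel_policy: str = "gray"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ConfigError(
                f"image data must be a 2-D matrix with h >= 1, w >= 1, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ConfigError("image data contains non-finite values")
        if arr.min() < 0 or arr.max() > self.max_gray:
            raise ConfigError(
                f"image values must lie in [0, {self.max_gray}], "
                f"got range [{arr.min()}, {arr.max()}]"
            )
        object.__setattr__(self, "data", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def h(self) -> int:
        return self.data.shape[0]

    @property
    def w(self) -> int:
        return self.data.shape[1]


def _max_gray_for_dtype(dtype: np.dtype) -> int:
    if dtype == np.uint8:
        return 255
    if dtype == np.uint16:
        return 65535
    raise ImageIOError(
        f"unsupported bit depth: dtype {dtype} (only 8-bit and 16-bit "
        "unsigned integer images are supported)"
    )


def reduce_channels(pixels: np.ndarray, channel_policy: str) -> np.ndarray:
    """Reduce an (h, w, 3) array to a single plane per the channel policy."""
    if channel_policy == "red":
        return pixels[..., 0].astype(np.float64)
    if channel_policy == "luminance":
        weights = np.asarray(LUMINANCE_WEIGHTS)
        return np.rint(pixels[..., :3].astype(np.float64) @ weights)
    raise ConfigError(
        f"channel_policy must be one of {CHANNEL_POLICIES}, got {channel_policy!r}"
    )


def load_image(path: str | Path, channel_policy: str = "red") -> ImageMatrix:
    """Read a PNG or TIFF strip image and extract the working gray matrix.

    Single-channel input ignores ``channel_policy`` (recorded as "gray");
    3-channel input is reduced per the policy.  Deterministic: the same
    file and policy always give the identical matrix.
    """
    if channel_policy not in ("red", "luminance"):
        raise ConfigError(
            f"channel_policy must be 'red' or 'luminance', got {channel_policy!r}"
        )
    import imageio.v3 as iio

    try:
        raw = iio.imread(Path(path))
    except FileNotFoundError as exc:
        raise ImageIOError(f"image file not found: {path}") from exc
    except Exception as exc:  # unreadable / undecodable
        raise ImageIOError(f"unreadable image file {path}: {exc}") from exc

    max_gray = _max_gray_for_dtype(raw.dtype)
    if raw.ndim == 2:
        return ImageMatrix(raw.astype(np.float64), max_gray, "gray")
    if raw.ndim == 3:
        if raw.shape[2] in (3, 4):  # alpha plane, if present, is ignored
            data = reduce_channels(raw[..., :3], channel_policy)
            return ImageMatrix(data, max_gray, channel_policy)
        raise ImageIOError(
            f"unsupported channel count {raw.shape[2]} in {path} "
            "(expected single-channel or 3-channel)"
        )
    raise ImageIOError(f"unsupported image dimensionality {raw.ndim} in {path}")


def result_records(
    results: Iterable["QuantResult"], max_gray: int
) -> list[dict]:
    """Flatten quantification results to plain-dict report records.

    ``avepix_relative`` is the paper-style relative fluorescence intensity,
    avePix normalized by the full-scale gray value.
    """
    records = []
    for i, res in enumerate(results):
        roi = res.roi
        records.append(
            {
                "signal": i,
                "mode": roi.mode,
                "x_left": int(roi.x_left),
                "x_right": int(roi.x_right),
                "top": int(roi.top),
                "down": int(roi.down),
                "apex_x": int(roi.apex_x),
                "apex_y": None if roi.apex_y is None else int(roi.apex_y),
                "avepix": float(res.avepix),
                "avepix_relative": float(res.avepix) / max_gray,
                "volume": float(res.volume),
                "n_rows_detected": int(sum(r.detected for r in res.rows)),
            }
        )
    return records


def write_result(
    results: Iterable["QuantResult"],
    path: str | Path,
    fmt: str = "json",
    *,
    max_gray: int = 255,
    metadata: dict | None = None,
    include_rows: bool = False,
) -> None:
    """Write a machine-readable quantification report (JSON or CSV).

    An empty result set produces a valid file with zero records.  The
    per-row boundary table (``dp_l``/``dp_r``/``baseval``/``area`` per
    scan line) is included on request (JSON only).
    """
    if fmt not in ("json", "csv"):
        raise ConfigError(f"format must be 'json' or 'csv', got {fmt!r}")
    results = list(results)
    records = result_records(results, max_gray)
    path = Path(path)
    try:
        if fmt == "csv":
            pd.DataFrame(
                records,
                columns=[
                    "signal", "mode", "x_left", "x_right", "top", "down",
                    "apex_x", "apex_y", "avepix", "avepix_relative",
                    "volume", "n_rows_detected",
                ],
            ).to_csv(path, index=False)
            return
        doc: dict = {"max_gray": max_gray, "signals": records}
        if metadata:
            doc["metadata"] = metadata
        if include_rows:
            for rec, res in zip(doc["signals"], results):
                rec["rows"] = [
                    {
                        "y": int(r.y),
                        "detected": bool(r.detected),
                        "dp_l": int(r.dp_l),
                        "dp_r": int(r.dp_r),
                        "baseval": float(r.baseval),
                        "area": float(r.area),
                    }
                    for r in res.rows
                ]
        path.write_text(json.dumps(doc, indent=1))
    except OSError as exc:
        raise ImageIOError(f"cannot write report to {path}: {exc}") from exc


def read_result(path: str | Path) -> dict:
    """Parse a JSON report written by :func:`write_result`."""
    try:
        return json.loads(Path(path).read_text())
    except OSError as exc:
        raise ImageIOError(f"cannot read report {path}: {exc}") from exc
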