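"""Directional projection curves.

A projection collapses a 2-D image region into a 1-D profile by summing
gray values along one axis: ``Y_j = sum_i y_ij``.  Summing (rather than
averaging) is deliberate — downstream peak validity thresholds are
positional, not amplitude-based, and the transform is scale-covariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .image_io import ImageMatrix

#: Collapse the row axis: one value per column (profile along X).
COLLAPSE_ROWS = "collapse_rows"
#: Collapse the column axis: one value per row (profile along Y).
COLLAPSE_COLS = "collapse_cols"


@dataclass(frozen=True)
class ProjectionCurve:
    """1-D profile from summing intensities along one axis.

    ``origin`` is the offset of index 0 in the source image along the
    retained axis, so sub-rectangle projections keep their coordinates.
    """

    values: np.ndarray
    axis: str
    origin: int = 0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 1 or vals.size < 1:
            raise ConfigError("projection curve must be 1-D and non-empty")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size


def _check_bounds(image: ImageMatrix, bounds: tuple[int, int, int, int]):
    top, down, left, right = bounds
    if not (0 <= top <= down < image.h and 0 <= left <= right < image.w):
        raise ConfigError(
            f"bounds (top={top}, down={down}, left={left}, right={right}) "
            f"empty or outside image of shape {image.shape}"
        )
    return top, down, left, right


def project(
    image: ImageMatrix,
    axis: str,
    bounds: tuple[int, int, int, int] | None = None,
) -> ProjectionCurve:
    """Project an image (or an inclusive sub-rectangle of it) along one axis.

    Parameters
    ----------
    axis : {"collapse_rows", "collapse_cols"}
        ``collapse_rows`` sums over rows, returning a per-column curve of
        length w; ``collapse_cols`` sums over columns, returning a
        per-row curve of length h.
    bounds : (top, down, left, right), optional
        Inclusive sub-rectangle; the curve's ``origin`` is set from it.
    """
    if bounds is None:
        top, down, left, right = 0, image.h - 1, 0, image.w - 1
    else:
        top, down, left, right = _check_bounds(image, tuple(bounds))
    block = image.data[top : down + 1, left : right + 1]
    if axis == COLLAPSE_ROWS:
        return ProjectionCurve(block.sum(axis=0), axis, origin=left)
    if axis == COLLAPSE_COLS:
        return ProjectionCurve(block.sum(axis=1), axis, origin=top)
    raise ConfigError(
        f"axis must be {COLLAPSE_ROWS!r} or {COLLAPSE_COLS!r}, got {axis!r}"
    )
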