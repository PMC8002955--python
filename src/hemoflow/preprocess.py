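"""Region-of-interest cropping, median denoising and polarity normalization.

These are the steps applied before segmentation: the analysis is restricted
to the channel interior, a median mask smooths the background while
preserving cell edges, and brightfield frames are inverted so that all
downstream stages can treat cells as bright objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["Rect", "crop", "median_filter", "normalize_polarity"]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in pixel coordinates (x0, y0 = top-left)."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("Rect width and height must be >= 1")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("Rect origin must be non-negative")

    @property
    def x1(self) -> int:
        return self.x0 + self.width

    @property
    def y1(self) -> int:
        return self.y0 + self.height


def crop(frame: np.ndarray, rect: Rect) -> np.ndarray:
    """Extract ``rect`` from ``frame``; the rectangle must lie fully inside."""
    h, w = frame.shape
    if rect.x1 > w or rect.y1 > h:
        raise ValueError(f"rect {rect} extends past frame bounds {h}x{w}")
    return frame[rect.y0 : rect.y1, rect.x0 : rect.x1]


def median_filter(frame: np.ndarray, kernel: int, pad: str = "replicate") -> np.ndarray:
    """Median-filter a frame with a square ``kernel`` x ``kernel`` mask.

    ``pad`` selects border handling: ``"replicate"`` (edge replication, the
    default — avoids the phantom dark borders zero padding creates on
    fluorescence frames) or ``"zero"`` for compatibility with tools that
    zero-pad.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("median kernel must be odd and >= 1")
    if pad == "replicate":
        return ndimage.median_filter(frame, size=kernel, mode="nearest")
    if pad == "zero":
        return ndimage.median_filter(frame, size=kernel, mode="constant", cval=0)
    raise ValueError("pad must be 'replicate' or 'zero'")


def normalize_polarity(frame: np.ndarray, mode: str, max_value: int | None = None) -> np.ndarray:
    """Return a frame in which cells are bright.

    Fluorescence frames pass through unchanged; brightfield frames are
    inverted (``max_value - pixel``).  ``max_value`` defaults to the dtype
    full scale (255 or 65535).
    """
    if mode == "fluorescence":
        return frame
    if mode != "brightfield":
        raise ValueError("mode must be 'fluorescence' or 'brightfield'")
    if max_value is None:
        max_value = int(np.iinfo(frame.dtype).max)
    return (max_value - frame).astype(frame.dtype)
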