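"""Temporal Z-projections and the ROI tonality (Z-axis) profile.

Re-creates the six ImageJ ZProject reductions — average, sum, standard
deviation, median, min, max — applied per pixel along the time axis, and the
Plot-Z-axis-profile tool, which records the mean intensity ("tonality") of a
region of interest in every frame.  In a microchannel recording high ROI
tonality corresponds to low local hematocrit: fewer cells, more plasma.

Projections are returned real-valued; conversion to a displayable 8-bit
image is an explicit separate step (:func:`rescale_to_8bit`), never implicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ImageStack
from .preprocess import Rect

__all__ = [
    "ProjectionImage",
    "ZAxisProfile",
    "z_project",
    "z_axis_profile",
    "rescale_to_8bit",
    "PROJECTION_METHODS",
]

PROJECTION_METHODS = ("average", "sum", "std", "median", "min", "max")


@dataclass(frozen=True)
class ProjectionImage:
    """Per-pixel temporal reduction of a stack; ``values`` is float64."""

    values: np.ndarray
    method: str


@dataclass(frozen=True)
class ZAxisProfile:
    """Mean ROI intensity per frame: list of (frame_index, mean)."""

    samples: list[tuple[int, float]]


def z_project(stack: ImageStack, method: str, sample_std: bool = True) -> ProjectionImage:
    """Project a stack along time with one of the six ZProject methods.

    ``std`` uses the sample (n-1) denominator by default, matching ImageJ;
    pass ``sample_std=False`` for the population (n) form.  The median of an
    even frame count is the mean of the two central values.
    """
    data = stack.data.astype(np.float64)
    if method == "average":
        out = data.mean(axis=0)
    elif method == "sum":
        out = data.sum(axis=0)
    elif method == "std":
        if sample_std and stack.n_frames < 2:
            raise ValueError("sample std needs >= 2 frames")
        out = data.std(axis=0, ddof=1 if sample_std else 0)
    elif method == "median":
        out = np.median(data, axis=0)
    elif method == "min":
        out = data.min(axis=0)
    elif method == "max":
        out = data.max(axis=0)
    else:
        raise ValueError(f"unknown projection method {method!r}; expected one of {PROJECTION_METHODS}")
    return ProjectionImage(values=out, method=method)


def z_axis_profile(stack: ImageStack, roi: Rect) -> ZAxisProfile:
    """Mean tonality of ``roi`` in every frame.

    High tonality corresponds to low hematocrit (plasma is brighter than
    cells in brightfield; in fluorescence the relation inverts with polarity).
    """
    h, w = stack.shape
    if roi.x1 > w or roi.y1 > h:
        raise ValueError(f"roi {roi} outside frame bounds {h}x{w}")
    sub = stack.data[:, roi.y0 : roi.y1, roi.x0 : roi.x1].astype(np.float64)
    means = sub.mean(axis=(1, 2))
    return ZAxisProfile(samples=[(f, float(m)) for f, m in enumerate(means)])


def rescale_to_8bit(projection: ProjectionImage) -> np.ndarray:
    """Linearly map a projection's value range onto 0..255 for display."""
    v = projection.values
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return np.zeros_like(v, dtype=np.uint8)
    return np.clip(np.round((v - lo) * 255.0 / (hi - lo)), 0, 255).astype(np.uint8)
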