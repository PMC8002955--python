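"""Threshold computation, binarization, Sobel edges, and wand selection.

The automatic threshold is the iterative intermeans scheme: starting from
the global mean, the level is repeatedly replaced by the midpoint of the
mean background intensity (pixels at or below the level) and the mean object
intensity (pixels above it),

    t_{k+1} = (mean{I <= t_k} + mean{I > t_k}) / 2,

until the update falls below a tolerance.  At the fixed point the threshold
equals the average of the background and object means, which is the
behaviour of ImageJ's default automatic threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.segmentation import flood

__all__ = [
    "ThresholdResult",
    "iterative_threshold",
    "binarize",
    "sobel_edges",
    "wand_select",
]


@dataclass(frozen=True)
class ThresholdResult:
    level: float
    iterations: int
    converged: bool


def iterative_threshold(frame: np.ndarray, tol: float = 0.5, max_iter: int = 100) -> ThresholdResult:
    """Intermeans threshold of a grayscale frame.

    Pixels at or below the level count as background, pixels above as
    objects (after polarity normalization objects are bright).  Raises on a
    constant frame, where no background/object split exists.
    """
    vals = np.asarray(frame, dtype=np.float64).ravel()
    if vals.size == 0:
        raise ValueError("empty frame")
    if vals.min() == vals.max():
        raise ValueError("constant frame: no threshold separates background from objects")
    t = float(vals.mean())
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        below = vals <= t
        t_new = (vals[below].mean() + vals[~below].mean()) / 2.0
        if abs(t_new - t) < tol:
            t = t_new
            converged = True
            break
        t = t_new
    return ThresholdResult(level=float(t), iterations=iterations, converged=converged)


def binarize(frame: np.ndarray, level: float) -> np.ndarray:
    """Boolean foreground mask: pixels strictly above ``level``."""
    return np.asarray(frame) > level


# Standard 3x3 Sobel kernels; Gx responds to horizontal intensity change.
_KX = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
_KY = _KX.T


def sobel_edges(frame: np.ndarray) -> np.ndarray:
    """Sobel gradient-magnitude image, sqrt(Gx^2 + Gy^2).

    The border is handled by edge replication.  The magnitude image shows
    the cell outlines; object extraction itself runs on the binarized frame,
    where filled components give better-defined centroids than edge rings.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2 or min(frame.shape) < 3:
        raise ValueError("frame must be 2-D and at least 3x3")
    gx = ndimage.correlate(frame, _KX, mode="nearest")
    gy = ndimage.correlate(frame, _KY, mode="nearest")
    return np.hypot(gx, gy)


def wand_select(frame: np.ndarray, seed_point: tuple[int, int], tolerance: float) -> np.ndarray:
    """Tolerance-based region selection (ImageJ Wand behaviour).

    Returns the maximal 8-connected set of pixels containing
    ``seed_point = (row, col)`` whose values lie within ``tolerance`` of the
    seed pixel's value.
    """
    frame = np.asarray(frame)
    r, c = seed_point
    if not (0 <= r < frame.shape[0] and 0 <= c < frame.shape[1]):
        raise ValueError(f"seed point {seed_point} outside frame {frame.shape}")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    # float cast so integer wrap-around cannot corrupt the |value - seed| test
    return flood(frame.astype(np.float64), (int(r), int(c)), tolerance=float(tolerance), connectivity=2)
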