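"""Automatic cell-free layer (CFL) thickness measurement.

In a brightfield microchannel recording red blood cells are dark on a
bright background, and a cell-depleted plasma margin — the cell-free layer
— hugs each wall.  The automatic method median-filters every frame, reduces
the sequence to a single cell-occupancy image in which every pixel a cell
ever traversed keeps the cell tonality while the CFL retains the bright
background, binarizes that image to a cell-core mask, and measures the
per-column distance from a user-supplied wall polyline to the first core
pixel.  Region summaries (mean/std over labelled column windows) support
comparison against manually measured profiles.

The cell-occupancy image is the pixelwise temporal extreme in the cell
direction: the minimum for brightfield stacks (dark cells), the maximum for
fluorescence stacks (bright cells).  For brightfield this is the image in
which the cell-free layer shows as the highest-intensity band along the
walls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ImageStack, RunConfig
from .preprocess import median_filter
from .projections import ProjectionImage, z_project
from .segmentation import iterative_threshold

__all__ = [
    "WallModel",
    "CFLProfile",
    "RegionSummary",
    "max_intensity_image",
    "cfl_binarize",
    "measure_cfl",
    "summarize_regions",
    "compare_methods",
    "measure_cfl_stack",
    "profile_to_frame",
    "summaries_to_frame",
]


@dataclass(frozen=True)
class WallModel:
    """One channel wall as a piecewise-linear polyline.

    ``polyline`` is a sequence of (x, y) vertices in pixel coordinates with
    strictly increasing x; the wall row at any column in the span is linear
    interpolation between vertices.  ``side`` states which wall this is:
    from an ``upper`` wall the layer is scanned downward (increasing row),
    from a ``lower`` wall upward.
    """

    side: str
    polyline: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.side not in ("upper", "lower"):
            raise ValueError("side must be 'upper' or 'lower'")
        xs = [p[0] for p in self.polyline]
        if len(xs) < 1:
            raise ValueError("polyline needs at least one vertex")
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValueError("polyline x coordinates must be strictly increasing")

    @property
    def span(self) -> tuple[int, int]:
        """Integer column range [x_start, x_end] covered by the polyline."""
        xs = [p[0] for p in self.polyline]
        return int(np.ceil(xs[0])), int(np.floor(xs[-1]))

    def wall_y(self, columns: np.ndarray) -> np.ndarray:
        xs = np.array([p[0] for p in self.polyline], dtype=float)
        ys = np.array([p[1] for p in self.polyline], dtype=float)
        return np.interp(np.asarray(columns, dtype=float), xs, ys)


@dataclass(frozen=True)
class CFLProfile:
    """Per-column CFL thickness along one wall; NaN where no core was found."""

    columns: np.ndarray
    thickness_px: np.ndarray
    pixel_size: float
    side: str

    @property
    def thickness_um(self) -> np.ndarray:
        return self.thickness_px * self.pixel_size


@dataclass(frozen=True)
class RegionSummary:
    region_label: str
    x_start: int
    x_end: int
    mean_um: float  # NaN when every column in the window is missing
    std_um: float
    n_columns: int


def max_intensity_image(stack: ImageStack, median_kernel: int = 0, pad: str = "replicate") -> ProjectionImage:
    """Cell-occupancy image of a stack (see module docstring).

    When ``median_kernel`` >= 3 each frame is median-filtered first, the
    denoising step of the automatic pipeline; 0 skips it (caller already
    denoised).
    """
    if median_kernel >= 3:
        data = np.stack([median_filter(f, median_kernel, pad=pad) for f in stack.frames])
        stack = stack.with_data(data)
    method = "min" if stack.mode == "brightfield" else "max"
    proj = z_project(stack, method)
    return ProjectionImage(values=proj.values, method=method)


def cfl_binarize(
    projection: ProjectionImage, level: Optional[float] = None, cells_dark: bool = True
) -> np.ndarray:
    """Binarize a cell-occupancy image into a cell-core mask.

    ``cells_dark=True`` (brightfield) marks pixels at or below the level as
    core; ``False`` (fluorescence) marks pixels above it.  ``level=None``
    computes the intermeans threshold automatically; a constant projection
    is degenerate and raises.
    """
    v = projection.values
    if level is None:
        level = iterative_threshold(v).level
    return (v <= level) if cells_dark else (v > level)


def measure_cfl(core_mask: np.ndarray, wall: WallModel, pixel_size: float = 1.0) -> CFLProfile:
    """Per-column layer thickness from the wall to the first core pixel.

    For an upper wall, thickness at column x is (row of first core pixel at
    or below the wall) - wall row; mirrored for a lower wall.  Columns whose
    scan meets no core pixel are reported missing (NaN), never clamped to 0.
    """
    h, w = core_mask.shape
    x0, x1 = wall.span
    if x0 < 0 or x1 >= w:
        raise ValueError(f"wall span [{x0}, {x1}] outside mask width {w}")
    cols = np.arange(x0, x1 + 1)
    wys = wall.wall_y(cols)
    if wys.min() < 0 or wys.max() > h - 1:
        raise ValueError("wall polyline leaves the frame")
    thickness = np.full(cols.shape, np.nan)
    for i, (x, wy) in enumerate(zip(cols, wys)):
        column = core_mask[:, x]
        if wall.side == "upper":
            rows = np.nonzero(column[int(np.ceil(wy)) :])[0]
            if rows.size:
                thickness[i] = (rows[0] + np.ceil(wy)) - wy
        else:
            rows = np.nonzero(column[: int(np.floor(wy)) + 1])[0]
            if rows.size:
                thickness[i] = wy - rows[-1]
    return CFLProfile(columns=cols, thickness_px=thickness, pixel_size=pixel_size, side=wall.side)


def summarize_regions(profile: CFLProfile, regions: Sequence[tuple[str, int, int]]) -> list[RegionSummary]:
    """Mean/std (n-1) of thickness over labelled column windows.

    ``regions`` holds (label, x_start, x_end) with inclusive bounds inside
    the profile span.  Missing columns are excluded from the statistics; a
    window with no measured column yields NaN mean/std.
    """
    out = []
    lo, hi = int(profile.columns[0]), int(profile.columns[-1])
    for label, x_start, x_end in regions:
        if x_start > x_end or x_start < lo or x_end > hi:
            raise ValueError(f"region {label!r} window [{x_start}, {x_end}] outside profile span [{lo}, {hi}]")
        sel = (profile.columns >= x_start) & (profile.columns <= x_end)
        vals = profile.thickness_um[sel]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            mean, std = float("nan"), float("nan")
        else:
            mean = float(vals.mean())
            std = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out.append(RegionSummary(label, x_start, x_end, mean, std, int(vals.size)))
    return out


def compare_methods(
    profile_auto: CFLProfile,
    profile_manual: CFLProfile,
    regions: Sequence[tuple[str, int, int]],
) -> dict:
    """Region-wise deltas and per-column rank correlation of two profiles.

    Both profiles must cover the same column span.  Returns per-region
    difference of means (auto - manual, um) and the Spearman rank
    correlation over columns where both profiles are measured.
    """
    if not np.array_equal(profile_auto.columns, profile_manual.columns):
        raise ValueError("profiles cover different column spans")
    auto = summarize_regions(profile_auto, regions)
    manual = summarize_regions(profile_manual, regions)
    deltas = {a.region_label: a.mean_um - m.mean_um for a, m in zip(auto, manual)}
    both = ~np.isnan(profile_auto.thickness_um) & ~np.isnan(profile_manual.thickness_um)
    if both.sum() >= 2:
        a, m = profile_auto.thickness_um[both], profile_manual.thickness_um[both]
        if np.ptp(a) == 0 and np.ptp(m) == 0:
            rho = 1.0 if np.allclose(a - m, (a - m)[0]) else float("nan")
        else:
            rho = float(stats.spearmanr(a, m).statistic)
    else:
        rho = float("nan")
    return {"region_deltas_um": deltas, "rank_correlation": rho, "n_common_columns": int(both.sum())}


def measure_cfl_stack(stack: ImageStack, wall: WallModel, config: RunConfig) -> tuple[CFLProfile, ProjectionImage]:
    """Full automatic CFL pipeline: median per frame, occupancy image,
    binarization, wall-referenced per-column measurement."""
    proj = max_intensity_image(stack, median_kernel=config.median_kernel, pad=config.median_pad)
    core = cfl_binarize(proj, level=config.threshold_level, cells_dark=stack.mode == "brightfield")
    return measure_cfl(core, wall, pixel_size=stack.pixel_size), proj


def profile_to_frame(profile: CFLProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "column": profile.columns,
            "thickness_px": profile.thickness_px,
            "thickness_um": profile.thickness_um,
        }
    )


def summaries_to_frame(summaries: Sequence[RegionSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region": s.region_label,
                "x_start": s.x_start,
                "x_end": s.x_end,
                "mean_um": s.mean_um,
                "std_um": s.std_um,
                "n_columns": s.n_columns,
            }
            for s in summaries
        ]
    )
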