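"""Synthetic microchannel scenes with ground truth.

Two generators emulate the two experimental setups so that every pipeline
stage can be tested without external recordings:

``simulate_capillary``
    Fluorescence-mode stacks of bright, labeled cells advected through a
    straight horizontal capillary (640x480 frames by default, emulating a
    100 um glass capillary imaged at 100 frames/s).  Cells are rendered as
    anisotropic Gaussian spots — soft edges and genuine sub-pixel centroids,
    which is what exercises the threshold and centroid estimators.  Cell
    density is kept low (cf. the ~12% hematocrit used experimentally to keep
    tracking errors down) and initial positions are rejection-sampled so no
    two cells ever approach within a merge distance; every ground-truth
    trajectory is then recoverable as exactly one track.

``simulate_cfl_channel``
    Brightfield-mode stacks of dark cells between two wall polylines with a
    prescribed cell-free layer profile ``cfl_true(x)`` (800x600 frames by
    default, emulating a bifurcation/confluence chip imaged at 200
    frames/s).  Cells are rendered as anti-aliased opaque disks: a disk's
    binarized rim falls on its true geometric boundary, so the temporal
    occupancy projection reproduces the prescribed layer edge sharply.  Each
    cell keeps a fixed normalized lateral coordinate u in [0, 1] mapped
    between the column-wise layer boundaries (following the boundary as a
    streamline would), and the u values are stratified with dedicated
    boundary-hugging cells so the core is filled and the true layer edge is
    sampled densely at every column.

Both generators are bit-deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .io import ImageStack
from .tracking import Track

__all__ = ["SceneParams", "GroundTruth", "simulate_capillary", "simulate_cfl_channel", "example_regions"]

CFLSpec = Union[float, Sequence[float], Callable[[np.ndarray], np.ndarray]]


@dataclass
class SceneParams:
    """Parameters of a synthetic scene; defaults depend on the generator.

    ``wall_upper``/``wall_lower`` are wall polylines as (x, y) vertex lists;
    a single row value means a straight horizontal wall.  ``cfl_true`` (CFL
    scenes) is a constant, a per-column array, or a callable of the column
    array, giving the true layer thickness in pixels at each wall.
    """

    width: int = 640
    height: int = 480
    n_frames: int = 50
    mode: str = "fluorescence"
    wall_upper: Union[float, Sequence[tuple[float, float]]] = 140.0
    wall_lower: Union[float, Sequence[tuple[float, float]]] = 340.0
    n_cells: int = 20
    cell_radius_px: float = 8.0
    eccentricity: float = 1.0  # sigma_x / sigma_y of the Gaussian spot
    v_max: float = 4.0  # px / frame
    velocity_profile: str = "poiseuille"  # or "plug"
    cfl_true: Optional[CFLSpec] = None
    background_level: float = 20.0
    cell_contrast: float = 200.0
    noise_sigma: float = 0.0
    pixel_size: float = 0.5  # um / px
    frame_interval: float = 0.01  # s / frame
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v_max <= 0:
            raise ValueError("v_max must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.velocity_profile not in ("plug", "poiseuille"):
            raise ValueError("velocity_profile must be 'plug' or 'poiseuille'")
        if self.n_frames < 1 or self.n_cells < 0:
            raise ValueError("need n_frames >= 1 and n_cells >= 0")

    def wall_rows(self, columns: np.ndarray, which: str) -> np.ndarray:
        spec = self.wall_upper if which == "upper" else self.wall_lower
        if np.isscalar(spec):
            return np.full(len(columns), float(spec))
        pts = np.asarray(spec, dtype=float)
        return np.interp(np.asarray(columns, dtype=float), pts[:, 0], pts[:, 1])


@dataclass
class GroundTruth:
    """True per-frame centroids per cell and, for CFL scenes, the true
    per-column layer thickness."""

    tracks: list[Track] = field(default_factory=list)
    cfl_profile: Optional[np.ndarray] = None


def _finalize(image: np.ndarray, params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    if params.noise_sigma > 0:
        image = image + rng.normal(0.0, params.noise_sigma, image.shape)
    return np.clip(np.round(image), 0, 255).astype(np.uint8)


def _velocity(params: SceneParams, y: float, y_center: float, channel_width: float) -> float:
    if params.velocity_profile == "plug":
        return params.v_max
    xi = 2.0 * (y - y_center) / channel_width
    return params.v_max * max(0.0, 1.0 - xi * xi)


def simulate_capillary(params: SceneParams) -> tuple[ImageStack, GroundTruth]:
    """Fluorescence capillary scene: bright Gaussian cells, parabolic flow.

    Initial positions are rejection-sampled so that no two cells come close
    enough to merge at any time during the sequence, and each cell stays
    fully in frame, so the returned truth tracks cover all frames.
    """
    if params.mode != "fluorescence":
        raise ValueError("capillary scenes are fluorescence-mode")
    wu = params.wall_rows(np.array([0]), "upper")[0]
    wl = params.wall_rows(np.array([0]), "lower")[0]
    if not (0 <= wu < wl <= params.height):
        raise ValueError("invalid channel geometry")
    rng = np.random.default_rng(params.seed)
    r = params.cell_radius_px
    sigma_y = r / 2.0
    sigma_x = sigma_y * params.eccentricity
    margin = 3.0 * max(sigma_x, sigma_y)
    y_center = (wu + wl) / 2.0
    chan_w = wl - wu
    travel_max = params.v_max * (params.n_frames - 1)
    x_hi = params.width - margin - travel_max
    if x_hi <= margin:
        raise ValueError("frame too narrow for the requested travel; lower v_max or n_frames")

    # rejection-sample starts: cells in a vertical band within a merge
    # distance must keep horizontal clearance for the whole sequence
    min_gap = 4.5 * r
    placed: list[tuple[float, float, float]] = []  # (x0, y0, v)
    for _ in range(params.n_cells):
        for _attempt in range(2000):
            y0 = rng.uniform(wu + 2 * r, wl - 2 * r)
            x0 = rng.uniform(margin, x_hi)
            v = _velocity(params, y0, y_center, chan_w)
            ok = True
            for px, py, pv in placed:
                if abs(y0 - py) >= min_gap:
                    continue
                d0 = abs(x0 - px)
                dT = abs((x0 + v * (params.n_frames - 1)) - (px + pv * (params.n_frames - 1)))
                if min(d0, dT) < min_gap:
                    ok = False
                    break
            if ok:
                placed.append((x0, y0, v))
                break
        else:
            raise ValueError("could not place cells without merge risk; lower n_cells")

    frames = np.empty((params.n_frames, params.height, params.width), dtype=np.uint8)
    tracks = [Track(track_id=i) for i in range(len(placed))]
    yy_cache = np.arange(params.height)
    xx_cache = np.arange(params.width)
    ext = int(np.ceil(4 * max(sigma_x, sigma_y)))
    for f in range(params.n_frames):
        img = np.full((params.height, params.width), params.background_level, dtype=np.float64)
        for i, (x0, y0, v) in enumerate(placed):
            cx = x0 + v * f
            cy = y0
            tracks[i].points.append((f, cx, cy))
            c0, c1 = int(np.floor(cx)) - ext, int(np.floor(cx)) + ext + 1
            r0, r1 = int(np.floor(cy)) - ext, int(np.floor(cy)) + ext + 1
            c0, c1 = max(c0, 0), min(c1, params.width)
            r0, r1 = max(r0, 0), min(r1, params.height)
            gx = np.exp(-((xx_cache[c0:c1] - cx) ** 2) / (2 * sigma_x**2))
            gy = np.exp(-((yy_cache[r0:r1] - cy) ** 2) / (2 * sigma_y**2))
            img[r0:r1, c0:c1] += params.cell_contrast * np.outer(gy, gx)
        frames[f] = _finalize(img, params, rng)
    stack = ImageStack(
        frames,
        pixel_size=params.pixel_size,
        frame_interval=params.frame_interval,
        mode="fluorescence",
    )
    return stack, GroundTruth(tracks=tracks)


def _resolve_cfl(spec: CFLSpec, columns: np.ndarray) -> np.ndarray:
    if callable(spec):
        out = np.asarray(spec(columns), dtype=float)
    elif np.isscalar(spec):
        out = np.full(len(columns), float(spec))
    else:
        out = np.asarray(spec, dtype=float)
        if out.shape != columns.shape:
            raise ValueError("cfl_true array must have one value per column")
    if (out < 0).any():
        raise ValueError("cfl_true must be >= 0")
    return out


def _cfl_default_params() -> dict:
    return dict(
        width=800,
        height=600,
        n_frames=200,
        mode="brightfield",
        wall_upper=150.0,
        wall_lower=450.0,
        n_cells=60,
        cell_radius_px=6.0,
        v_max=5.0,
        velocity_profile="plug",
        cfl_true=15.0,
        background_level=230.0,
        cell_contrast=180.0,
        pixel_size=1.0,
        frame_interval=0.005,
    )


def cfl_scene_params(**overrides) -> SceneParams:
    """SceneParams pre-filled with the brightfield CFL-scene defaults."""
    kw = _cfl_default_params()
    kw.update(overrides)
    return SceneParams(**kw)


def simulate_cfl_channel(params: SceneParams) -> tuple[ImageStack, GroundTruth]:
    """Brightfield channel scene with a prescribed cell-free layer.

    Dark disk cells are confined between ``wall + cfl_true(x)`` and the
    mirrored lower boundary.  Lateral positions are stratified in the
    normalized coordinate u, with a contingent of boundary-hugging cells
    (u = 0 and u = 1) at random flow phases so the true layer edge is
    attained at every column.  Cells advect in x and wrap around, keeping
    the core populated throughout the sequence.
    """
    if params.mode != "brightfield":
        raise ValueError("CFL scenes are brightfield-mode")
    if params.cfl_true is None:
        raise ValueError("cfl_true is required for a CFL scene")
    rng = np.random.default_rng(params.seed)
    cols = np.arange(params.width)
    wu = params.wall_rows(cols, "upper")
    wl = params.wall_rows(cols, "lower")
    if (wu >= wl).any():
        raise ValueError("upper wall must stay above lower wall")
    cfl = _resolve_cfl(params.cfl_true, cols)
    r = params.cell_radius_px
    top = wu + cfl + r  # column-wise band available to cell centres
    bot = wl - cfl - r
    if (bot < top).any():
        raise ValueError("cfl_true exceeds half the channel height somewhere")

    n = params.n_cells
    n_edge = max(2, n // 10)  # boundary-hugging contingent per wall
    n_core = max(0, n - 2 * n_edge)
    u = np.concatenate(
        [
            np.zeros(n_edge),
            np.ones(n_edge),
            (np.arange(n_core) + rng.uniform(0.2, 0.8, n_core)) / max(n_core, 1),
        ]
    )
    x0 = rng.uniform(0, params.width, n)
    period = params.width + 2 * r  # wrap period; cells re-enter from the left

    frames = np.empty((params.n_frames, params.height, params.width), dtype=np.uint8)
    ri = int(np.ceil(r + 0.5))
    yy = np.arange(params.height)
    for f in range(params.n_frames):
        img = np.full((params.height, params.width), params.background_level, dtype=np.float64)
        xs = (x0 + params.v_max * f + r) % period - r
        for i in range(n):
            cx = xs[i]
            col = int(np.clip(np.round(cx), 0, params.width - 1))
            cy = top[col] + u[i] * (bot[col] - top[col])
            c0, c1 = max(int(np.floor(cx)) - ri, 0), min(int(np.floor(cx)) + ri + 1, params.width)
            r0, r1 = max(int(np.floor(cy)) - ri, 0), min(int(np.floor(cy)) + ri + 1, params.height)
            if c0 >= c1 or r0 >= r1:
                continue
            dist = np.hypot(
                np.arange(c0, c1)[None, :] - cx, yy[r0:r1, None].astype(float) - cy
            )
            coverage = np.clip(r + 0.5 - dist, 0.0, 1.0)  # anti-aliased opaque disk
            patch = params.background_level - params.cell_contrast * coverage
            img[r0:r1, c0:c1] = np.minimum(img[r0:r1, c0:c1], patch)
        frames[f] = _finalize(img, params, rng)
    stack = ImageStack(
        frames,
        pixel_size=params.pixel_size,
        frame_interval=params.frame_interval,
        mode="brightfield",
    )
    return stack, GroundTruth(cfl_profile=cfl)


def example_regions(width: int, n_regions: int = 6, margin: int = 10) -> list[tuple[str, int, int]]:
    """Six equal labelled column windows (A..F) across a scene width —
    the packaged example layout for region-wise CFL reporting."""
    labels = [chr(ord("A") + i) for i in range(n_regions)]
    edges = np.linspace(margin, width - 1 - margin, n_regions + 1).astype(int)
    return [(labels[i], int(edges[i]), int(edges[i + 1] - (1 if i < n_regions - 1 else 0))) for i in range(n_regions)]
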