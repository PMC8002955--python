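"""Reading and writing of image stacks, track tables and run configuration.

An :class:`ImageStack` is the package's central container: an ordered set of
equally sized grayscale frames together with the spatial calibration
(micrometres per pixel), the temporal calibration (seconds per frame) and the
imaging mode.  Two modes are supported:

* ``fluorescence`` — labeled cells appear *bright* on a dark background
  (confocal capillary recordings);
* ``brightfield`` — cells appear *dark* on a bright background, with a bright
  cell-free margin near the channel walls.

Coordinates are image-convention and 0-based throughout: ``x`` is the column
index increasing rightward, ``y`` the row index increasing downward.
Calibration is applied only on export (``x_um = x_px * pixel_size``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "RunConfig",
    "read_stack",
    "write_stack",
    "write_tracks",
    "read_tracks",
    "read_config",
]

_MODES = ("fluorescence", "brightfield")

#: file extensions accepted when reading a directory of single-frame images
_FRAME_EXTS = (".tif", ".tiff", ".png", ".bmp")


@dataclass
class ImageStack:
    """Ordered grayscale frames plus calibration.

    Parameters
    ----------
    data
        Array of shape ``(n_frames, height, width)``, dtype ``uint8`` or
        ``uint16``.
    pixel_size
        Micrometres per pixel, > 0.
    frame_interval
        Seconds per frame, > 0.
    mode
        ``"fluorescence"`` (cells bright) or ``"brightfield"`` (cells dark).
    """

    data: np.ndarray
    pixel_size: float = 1.0
    frame_interval: float = 1.0
    mode: str = "fluorescence"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("stack needs >= 1 frame of identical 2-D shape")
        if self.data.dtype not in (np.uint8, np.uint16):
            raise ValueError(f"unsupported dtype {self.data.dtype}; expected uint8 or uint16")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of every frame."""
        return self.data.shape[1:]

    @property
    def bit_depth(self) -> int:
        return 8 if self.data.dtype == np.uint8 else 16

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def frames(self) -> np.ndarray:
        """The frame array (read as ``stack.frames[i]`` for frame *i*)."""
        return self.data

    def with_data(self, data: np.ndarray) -> "ImageStack":
        """A copy of this stack carrying ``data`` but the same calibration."""
        return replace(self, data=data)


@dataclass
class RunConfig:
    """Resolved parameters for a tracking or CFL run.

    Defaults follow the automatic pipelines: a 5x5 median mask and an
    iteratively computed threshold for tracking, inclusive area bounds to
    reject platelets (too small) and white blood cells (too large), a hard
    displacement gate for frame-to-frame linking, and removal of tracks with
    fewer than ``min_track_length`` positions.
    """

    median_kernel: int = 5
    threshold_level: Optional[float] = None  # None -> iterative (automatic)
    area_min: float = 10.0
    area_max: float = 500.0
    link_max_displacement: float = 10.0
    min_track_length: int = 10
    connectivity: int = 8
    roi: Optional[tuple[int, int, int, int]] = None  # x0, y0, width, height
    median_pad: str = "replicate"  # or "zero"
    wall: Optional[list[tuple[float, float]]] = None  # polyline (x, y) pairs
    wall_side: str = "upper"
    regions: list[tuple[str, int, int]] = field(default_factory=list)
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 1")
        if self.area_min > self.area_max:
            raise ValueError("area_min must be <= area_max")
        if self.min_track_length < 1:
            raise ValueError("min_track_length must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.median_pad not in ("replicate", "zero"):
            raise ValueError("median_pad must be 'replicate' or 'zero'")


def _as_gray(frame: np.ndarray, path: object) -> np.ndarray:
    if frame.ndim == 3:  # collapse trivial colour axes (e.g. palette PNG)
        if frame.shape[2] in (3, 4) and np.ptp(frame[..., :3], axis=2).max() == 0:
            frame = frame[..., 0]
        else:
            raise ValueError(f"{path}: colour images are not supported")
    if frame.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale frame")
    if frame.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"{path}: unsupported bit depth {frame.dtype}")
    return frame


def read_stack(
    path: str | os.PathLike,
    pixel_size: float = 1.0,
    frame_interval: float = 1.0,
    mode: str = "fluorescence",
) -> ImageStack:
    """Read a multi-page TIFF or a directory of single-frame images.

    Directory frames are taken in lexicographic filename order; every frame
    must share dimensions and dtype.
    """
    p = Path(path)
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.suffix.lower() in _FRAME_EXTS)
        if not files:
            raise ValueError(f"{p}: no image files found")
        frames = [_as_gray(iio.imread(f), f) for f in files]
    else:
        if not p.exists():
            raise FileNotFoundError(str(p))
        arr = tifffile.imread(str(p))
        if arr.ndim == 2:
            arr = arr[None]
        frames = [_as_gray(f, p) for f in arr]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"{p}: frames have mismatched sizes {sorted(shapes)}")
    dtypes = {f.dtype for f in frames}
    if len(dtypes) != 1:
        raise ValueError(f"{p}: frames have mismatched dtypes")
    return ImageStack(
        np.stack(frames), pixel_size=pixel_size, frame_interval=frame_interval, mode=mode
    )


def write_stack(stack: ImageStack, path: str | os.PathLike) -> None:
    """Write a stack as a multi-page TIFF; round-trips bit-exactly."""
    tifffile.imwrite(str(path), stack.data, photometric="minisblack")


def write_tracks(tracks: Sequence, pixel_size: float, path: str | os.PathLike) -> None:
    """Write trajectories as a CSV table of calibrated points.

    Columns: ``track_id, frame, x_px, y_px, x_um, y_um`` with
    ``x_um = x_px * pixel_size``; one row per tracked point, sorted by
    ``(track_id, frame)``.
    """
    rows = []
    for tr in tracks:
        for f, x, y in tr.points:
            rows.append((tr.track_id, f, x, y, x * pixel_size, y * pixel_size))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x_px", "y_px", "x_um", "y_um"])
    df = df.sort_values(["track_id", "frame"], kind="stable")
    df.to_csv(path, index=False)


def read_tracks(path: str | os.PathLike):
    """Read a track table written by :func:`write_tracks` back into Tracks."""
    from .tracking import Track

    df = pd.read_csv(path)
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        pts = [(int(f), float(x), float(y)) for f, x, y in zip(g.frame, g.x_px, g.y_px)]
        tracks.append(Track(track_id=int(tid), points=pts))
    return tracks


def _parse_value(key: str, raw: str):
    raw = raw.strip()
    if key == "roi":
        return tuple(int(v) for v in raw.split(","))
    if key in ("median_kernel", "min_track_length", "connectivity", "random_seed"):
        return int(raw)
    if key in ("threshold_level", "area_min", "area_max", "link_max_displacement"):
        return None if raw.lower() == "auto" else float(raw)
    return raw


def read_config(path: str | os.PathLike) -> RunConfig:
    """Parse a flat ``key = value`` text file into a :class:`RunConfig`.

    Unknown keys are rejected so typos fail loudly; ``#`` starts a comment.
    """
    kwargs = {}
    valid = set(RunConfig.__dataclass_fields__)
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, raw = (s.strip() for s in line.split("=", 1))
        if key not in valid:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        kwargs[key] = _parse_value(key, raw)
    return RunConfig(**kwargs)
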