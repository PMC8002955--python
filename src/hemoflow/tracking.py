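"""Cell detection, trajectory linking and trajectory statistics.

Detection labels connected foreground components and measures their area,
centroid and bounding box (cf. MATLAB ``regionprops``).  Area bounds reject
non-RBC objects — platelets (smaller) and white blood cells (larger).
Linking is greedy globally-nearest-pair with a hard displacement gate:
per frame transition the unassigned (track, blob) pair at smallest centroid
distance is matched repeatedly while the distance stays within the gate;
unmatched blobs open new tracks and unmatched tracks terminate (no gap
closing).  Short fragments are eliminated by a minimum-track-length filter.

Trajectory statistics follow the standard conventions: the time-averaged
mean squared displacement

    MSD(tau) = < (x(t+tau) - x(t))^2 + (y(t+tau) - y(t))^2 > * pixel_size^2

and the lateral (wall-normal) dispersion coefficient

    Dyy(t) = < (y(t) - y(0))^2 > * pixel_size^2 / (2 * t * frame_interval),

the average running over tracks, with t counted in frames from each track's
start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage import measure

from .io import ImageStack, RunConfig
from .preprocess import Rect, crop, median_filter, normalize_polarity
from .segmentation import binarize, iterative_threshold

__all__ = [
    "Blob",
    "Track",
    "extract_blobs",
    "filter_by_area",
    "link_tracks",
    "filter_by_track_length",
    "msd",
    "radial_dispersion",
    "detect_stack",
    "track_stack",
    "match_to_reference",
]


@dataclass(frozen=True)
class Blob:
    """One connected component in one frame.

    ``centroid`` is (x, y) = (mean column, mean row) of the member pixels,
    sub-pixel; ``bbox`` is the tight bounding rectangle.
    """

    frame_index: int
    area: int
    centroid: tuple[float, float]
    bbox: Rect
    label: int


@dataclass
class Track:
    """One cell's trajectory: time-ordered (frame_index, x, y) points."""

    track_id: int
    points: list[tuple[int, float, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def frames(self) -> list[int]:
        return [p[0] for p in self.points]

    def position(self, frame: int) -> Optional[tuple[float, float]]:
        for f, x, y in self.points:
            if f == frame:
                return (x, y)
        return None


def extract_blobs(binary_frame: np.ndarray, connectivity: int = 8, frame_index: int = 0) -> list[Blob]:
    """Label connected foreground components and measure their properties."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    lab = measure.label(np.asarray(binary_frame, dtype=bool), connectivity=1 if connectivity == 4 else 2)
    blobs = []
    for rp in measure.regionprops(lab):
        r0, c0, r1, c1 = rp.bbox
        cy, cx = rp.centroid  # (row, col) -> (y, x)
        blobs.append(
            Blob(
                frame_index=frame_index,
                area=int(rp.area),
                centroid=(float(cx), float(cy)),
                bbox=Rect(x0=int(c0), y0=int(r0), width=int(c1 - c0), height=int(r1 - r0)),
                label=int(rp.label),
            )
        )
    return blobs


def filter_by_area(blobs: Sequence[Blob], area_min: float, area_max: float) -> list[Blob]:
    """Keep blobs with area in the inclusive interval [area_min, area_max]."""
    if area_min > area_max:
        raise ValueError("area_min must be <= area_max")
    return [b for b in blobs if area_min <= b.area <= area_max]


def link_tracks(blobs_per_frame: Sequence[Sequence[Blob]], link_max_displacement: float) -> list[Track]:
    """Link per-frame detections into trajectories.

    Greedy globally-nearest-pair assignment with a hard gate; distance ties
    broken by lower track_id, then lower blob label, making the result
    independent of per-frame blob ordering.  No gap closing: a track not
    matched in a transition terminates.
    """
    tracks: list[Track] = []
    active: list[Track] = []

    def _start(frame: int, blobs: Sequence[Blob]) -> list[Track]:
        new = []
        for b in sorted(blobs, key=lambda b: b.label):
            t = Track(track_id=len(tracks), points=[(frame, *b.centroid)])
            tracks.append(t)
            new.append(t)
        return new

    for f, blobs in enumerate(blobs_per_frame):
        if f == 0:
            active = _start(f, blobs)
            continue
        # candidate (distance, track_id, blob label) pairs within the gate
        pairs = []
        for t in active:
            _, tx, ty = t.points[-1]
            for b in blobs:
                bx, by = b.centroid
                d = float(np.hypot(bx - tx, by - ty))
                if d <= link_max_displacement:
                    pairs.append((d, t.track_id, b.label, t, b))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used_tracks: set[int] = set()
        used_blobs: set[int] = set()
        matched: list[Track] = []
        for d, tid, blabel, t, b in pairs:
            if tid in used_tracks or blabel in used_blobs:
                continue
            used_tracks.add(tid)
            used_blobs.add(blabel)
            t.points.append((f, *b.centroid))
            matched.append(t)
        leftovers = [b for b in blobs if b.label not in used_blobs]
        active = matched + _start(f, leftovers)
    return tracks


def filter_by_track_length(tracks: Sequence[Track], min_track_length: int) -> list[Track]:
    """Drop tracks with fewer than ``min_track_length`` points (inclusive keep)."""
    if min_track_length < 1:
        raise ValueError("min_track_length must be >= 1")
    return [t for t in tracks if len(t) >= min_track_length]


def msd(track: Track, pixel_size: float = 1.0) -> list[tuple[int, float]]:
    """Time-averaged mean squared displacement per integer frame lag.

    For each lag tau = 1..span, averages the squared displacement over all
    point pairs whose frame difference equals tau; returned in um^2.
    """
    if len(track) < 2:
        raise ValueError("track must have at least 2 points")
    pts = {f: (x, y) for f, x, y in track.points}
    frames = sorted(pts)
    span = frames[-1] - frames[0]
    out = []
    for tau in range(1, span + 1):
        sq = [
            (pts[f + tau][0] - pts[f][0]) ** 2 + (pts[f + tau][1] - pts[f][1]) ** 2
            for f in frames
            if f + tau in pts
        ]
        if sq:
            out.append((tau, float(np.mean(sq)) * pixel_size**2))
    return out


def radial_dispersion(
    tracks: Sequence[Track], pixel_size: float = 1.0, frame_interval: float = 1.0
) -> list[tuple[float, float]]:
    """Lateral dispersion coefficient Dyy versus elapsed time.

    For each elapsed time t (in frames from each track's start),
    Dyy = <(y(t)-y(0))^2> * pixel_size^2 / (2 * t * frame_interval), the mean
    running over tracks that extend to t.  Times are returned in seconds,
    Dyy in um^2/s.
    """
    usable = [t for t in tracks if len(t) >= 2]
    if not usable:
        raise ValueError("need at least one track with >= 2 points")
    max_off = max(t.points[-1][0] - t.points[0][0] for t in usable)
    out = []
    for off in range(1, max_off + 1):
        dy2 = []
        for t in usable:
            f0, _, y0 = t.points[0]
            pos = t.position(f0 + off)
            if pos is not None:
                dy2.append((pos[1] - y0) ** 2)
        if dy2:
            elapsed = off * frame_interval
            out.append((elapsed, float(np.mean(dy2)) * pixel_size**2 / (2.0 * elapsed)))
    return out


def detect_stack(stack: ImageStack, config: RunConfig) -> list[list[Blob]]:
    """Per-frame detection: crop, median filter, polarity, threshold, label.

    The threshold is recomputed per frame by the iterative method unless
    ``config.threshold_level`` overrides it.
    """
    roi = Rect(*config.roi) if config.roi is not None else None
    blobs_per_frame: list[list[Blob]] = []
    for f in range(stack.n_frames):
        frame = stack.frames[f]
        if roi is not None:
            frame = crop(frame, roi)
        frame = median_filter(frame, config.median_kernel, pad=config.median_pad)
        frame = normalize_polarity(frame, stack.mode, max_value=stack.max_value)
        if config.threshold_level is not None:
            level = config.threshold_level
        else:
            level = iterative_threshold(frame).level
        blobs = extract_blobs(binarize(frame, level), config.connectivity, frame_index=f)
        blobs_per_frame.append(filter_by_area(blobs, config.area_min, config.area_max))
    return blobs_per_frame


def track_stack(stack: ImageStack, config: RunConfig) -> list[Track]:
    """Full automatic tracking pipeline on a stack; returns surviving tracks."""
    blobs_per_frame = detect_stack(stack, config)
    tracks = link_tracks(blobs_per_frame, config.link_max_displacement)
    return filter_by_track_length(tracks, config.min_track_length)


def match_to_reference(
    reference: Sequence[Track], candidates: Sequence[Track], tol: float = 2.0
) -> dict:
    """Compare trajectories against a reference set (ground truth or manual).

    Each reference track is matched to the candidate track holding the most
    of its positions within ``tol`` pixels (each candidate claimed by at most
    one reference track, best overlap first).  Returns per-position recall,
    the fraction of reference tracks recovered by exactly one full-coverage
    candidate, and the RMSE of matched positions.
    """
    # overlap counts between every (reference, candidate) pair
    scored = []
    for ri, ref in enumerate(reference):
        for ci, cand in enumerate(candidates):
            cpts = {f: (x, y) for f, x, y in cand.points}
            hits = sum(
                1
                for f, x, y in ref.points
                if f in cpts and np.hypot(cpts[f][0] - x, cpts[f][1] - y) <= tol
            )
            if hits:
                scored.append((hits, ri, ci))
    scored.sort(key=lambda s: (-s[0], s[1], s[2]))
    ref_match: dict[int, int] = {}
    used: set[int] = set()
    for hits, ri, ci in scored:
        if ri in ref_match or ci in used:
            continue
        ref_match[ri] = ci
        used.add(ci)

    total = sum(len(r) for r in reference)
    recovered = 0
    complete = 0
    errs = []
    for ri, ref in enumerate(reference):
        ci = ref_match.get(ri)
        if ci is None:
            continue
        cpts = {f: (x, y) for f, x, y in candidates[ci].points}
        n_hit = 0
        for f, x, y in ref.points:
            if f in cpts:
                e = float(np.hypot(cpts[f][0] - x, cpts[f][1] - y))
                if e <= tol:
                    n_hit += 1
                    errs.append(e)
        recovered += n_hit
        if n_hit == len(ref):
            complete += 1
    return {
        "position_recall": recovered / total if total else 1.0,
        "complete_track_fraction": complete / len(reference) if reference else 1.0,
        "rmse_px": float(np.sqrt(np.mean(np.square(errs)))) if errs else 0.0,
        "max_err_px": float(max(errs)) if errs else 0.0,
        "n_reference_positions": total,
    }
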