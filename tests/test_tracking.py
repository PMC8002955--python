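from collections import deque
from itertools import permutations

import numpy as np
import pytest

from hemoflow.io import RunConfig
from hemoflow.synthetic import SceneParams, simulate_capillary
from hemoflow.tracking import (
    Blob,
    Track,
    extract_blobs,
    filter_by_area,
    filter_by_track_length,
    link_tracks,
    match_to_reference,
    msd,
    radial_dispersion,
    track_stack,
)
from hemoflow.preprocess import Rect


def components_oracle(binary, connectivity):
    """BFS flood-fill components: list of (area, centroid_x, centroid_y)."""
    h, w = binary.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros((h, w), dtype=bool)
    comps = []
    for r0 in range(h):
        for c0 in range(w):
            if binary[r0, c0] and not seen[r0, c0]:
                q = deque([(r0, c0)])
                seen[r0, c0] = True
                members = []
                while q:
                    r, c = q.popleft()
                    members.append((r, c))
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and binary[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            q.append((rr, cc))
                xs = [c for _, c in members]
                ys = [r for r, _ in members]
                comps.append((len(members), sum(xs) / len(xs), sum(ys) / len(ys)))
    return sorted(comps)


class TestExtractBlobs:
    def test_empty_frame(self):
        assert extract_blobs(np.zeros((5, 5), dtype=bool)) == []

    def test_filled_square_centroid(self):
        frame = np.zeros((10, 10), dtype=bool)
        frame[2:5, 5:8] = True
        (blob,) = extract_blobs(frame)
        assert blob.area == 9
        assert blob.centroid == (6.0, 3.0)
        assert blob.bbox == Rect(x0=5, y0=2, width=3, height=3)

    def test_diagonal_touch_depends_on_connectivity(self):
        frame = np.zeros((4, 4), dtype=bool)
        frame[1, 1] = frame[2, 2] = True
        assert len(extract_blobs(frame, connectivity=8)) == 1
        assert len(extract_blobs(frame, connectivity=4)) == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(100):
            frame = rng.random((10, 10)) < 0.4
            blobs = extract_blobs(frame, connectivity=connectivity)
            got = sorted((b.area, b.centroid[0], b.centroid[1]) for b in blobs)
            assert got == pytest.approx(components_oracle(frame, connectivity))
            assert sum(b.area for b in blobs) == int(frame.sum())  # conservation


class TestFilterByArea:
    def test_interval_membership(self):
        blobs = [Blob(0, a, (0.0, 0.0), Rect(0, 0, 1, 1), i) for i, a in enumerate([3, 25, 500])]
        assert [b.area for b in filter_by_area(blobs, 10, 100)] == [25]

    def test_wide_bounds_identity_and_inclusive_edge(self):
        blobs = [Blob(0, a, (0.0, 0.0), Rect(0, 0, 1, 1), i) for i, a in enumerate([1, 10, 99])]
        assert filter_by_area(blobs, 0, np.inf) == blobs
        assert [b.area for b in filter_by_area(blobs, 10, 99)] == [10, 99]


def _blob(x, y, label=0, frame=0):
    return Blob(frame, 1, (float(x), float(y)), Rect(max(int(x), 0), max(int(y), 0), 1, 1), label)


class TestLinkTracks:
    def test_single_moving_blob(self):
        frames = [[_blob(10 + 2 * f, 20, label=1, frame=f)] for f in range(5)]
        tracks = link_tracks(frames, link_max_displacement=5)
        assert len(tracks) == 1
        assert tracks[0].points == [(f, 10.0 + 2 * f, 20.0) for f in range(5)]

    def test_gate_prevents_identity_swap(self):
        frames = [
            [_blob(10 + f, 0, label=1, frame=f), _blob(10 + f, 100, label=2, frame=f)]
            for f in range(4)
        ]
        tracks = link_tracks(frames, link_max_displacement=5)
        assert len(tracks) == 2
        ys = sorted({p[2] for t in tracks for p in t.points})
        for t in tracks:
            assert len({p[2] for p in t.points}) == 1  # no swap across the gap
        assert ys == [0.0, 100.0]

    def test_matches_optimal_assignment_when_closest_pair_is_optimal(self, rng):
        # two tracks, two approaching blobs, each near its own predecessor:
        # the optimal matching contains the globally closest pair, so the
        # greedy result must equal exhaustive minimum-total-distance search
        for _ in range(50):
            p = [np.array([0.0, 0.0]), np.array([10.0, 0.0])]
            q = [pi + rng.uniform(-2, 2, 2) for pi in p]
            frames = [
                [_blob(*p[0], label=1), _blob(*p[1], label=2)],
                [_blob(*q[0], label=1, frame=1), _blob(*q[1], label=2, frame=1)],
            ]
            tracks = link_tracks(frames, link_max_displacement=6)
            got = {tuple(t.points[0][1:]): tuple(t.points[1][1:]) for t in tracks if len(t) == 2}
            best, best_cost = None, np.inf
            for perm in permutations(range(2)):
                cost = sum(np.linalg.norm(q[perm[i]] - p[i]) for i in range(2))
                if cost < best_cost:
                    best_cost, best = cost, {tuple(p[i]): tuple(q[perm[i]]) for i in range(2)}
            assert got == best

    def test_unmatched_blob_starts_new_track(self):
        frames = [[_blob(0, 0, label=1)], [_blob(0, 0, label=1, frame=1), _blob(50, 50, label=2, frame=1)]]
        tracks = link_tracks(frames, link_max_displacement=5)
        lengths = sorted(len(t) for t in tracks)
        assert lengths == [1, 2]

    def test_permutation_invariant_to_blob_order(self, rng):
        frames = []
        for f in range(4):
            blobs = [_blob(10 * i + f, 5 * i, label=i + 1, frame=f) for i in range(4)]
            frames.append(blobs)
        ref = link_tracks(frames, link_max_displacement=3)
        shuffled = [list(rng.permutation(len(fr))) for fr in frames]
        frames2 = [[fr[i] for i in order] for fr, order in zip(frames, shuffled)]
        alt = link_tracks(frames2, link_max_displacement=3)
        assert sorted(t.points for t in ref) == sorted(t.points for t in alt)


class TestTrackLengthFilter:
    def test_inclusive_threshold(self):
        tracks = [Track(i, [(f, 0.0, 0.0) for f in range(n)]) for i, n in enumerate([3, 10, 50])]
        assert [len(t) for t in filter_by_track_length(tracks, 10)] == [10, 50]
        assert filter_by_track_length(tracks, 1) == tracks
        assert filter_by_track_length([], 5) == []


class TestMsd:
    def test_stationary_track_is_zero(self):
        track = Track(0, [(f, 3.0, 4.0) for f in range(6)])
        assert all(v == 0 for _, v in msd(track))

    def test_ballistic_closed_form(self):
        v = 1.7
        track = Track(0, [(f, v * f, 2.0) for f in range(8)])
        for tau, val in msd(track, pixel_size=1.0):
            assert val == pytest.approx((v * tau) ** 2, rel=1e-9)

    def test_three_four_five(self):
        assert msd(Track(0, [(0, 0.0, 0.0), (1, 3.0, 4.0)])) == [(1, pytest.approx(25.0))]

    def test_matches_brute_force_double_loop(self, rng):
        pts = [(f, float(x), float(y)) for f, (x, y) in enumerate(rng.uniform(0, 50, (12, 2)))]
        track = Track(0, pts)
        got = dict(msd(track, pixel_size=0.5))
        for tau in range(1, 12):
            sq = [
                ((pts[i + tau][1] - pts[i][1]) ** 2 + (pts[i + tau][2] - pts[i][2]) ** 2) * 0.25
                for i in range(12 - tau)
            ]
            assert got[tau] == pytest.approx(np.mean(sq), rel=1e-12)

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            msd(Track(0, [(0, 0.0, 0.0)]))


class TestRadialDispersion:
    def test_constant_y_is_zero(self):
        tracks = [Track(i, [(f, float(f), 7.0) for f in range(5)]) for i in range(3)]
        assert all(v == 0 for _, v in radial_dispersion(tracks))

    def test_direct_substitution(self):
        track = Track(0, [(0, 0.0, 0.0), (1, 0.0, 2.0)])
        assert radial_dispersion([track], pixel_size=1.0, frame_interval=1.0) == [
            (1.0, pytest.approx(2.0))
        ]

    def test_pixel_size_squared_scaling(self, rng):
        pts = [(f, 0.0, float(y)) for f, y in enumerate(rng.uniform(0, 10, 6))]
        tracks = [Track(0, pts)]
        base = radial_dispersion(tracks, pixel_size=1.0)
        doubled = radial_dispersion(tracks, pixel_size=2.0)
        for (_, a), (_, b) in zip(base, doubled):
            assert b == pytest.approx(4 * a, rel=1e-12)

    def test_no_usable_track_rejected(self):
        with pytest.raises(ValueError):
            radial_dispersion([Track(0, [(0, 0.0, 0.0)])])


class TestPipeline:
    def test_small_scene_recovers_all_truth_tracks(self):
        params = SceneParams(width=320, height=240, n_frames=15, n_cells=6,
                             wall_upper=60, wall_lower=180, v_max=3.0, seed=11)
        stack, truth = simulate_capillary(params)
        cfg = RunConfig(link_max_displacement=2 * params.v_max, min_track_length=15)
        tracks = track_stack(stack, cfg)
        assert len(tracks) == 6
        report = match_to_reference(truth.tracks, tracks, tol=0.5)
        assert report["position_recall"] == 1.0
        assert report["complete_track_fraction"] == 1.0
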