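"""Detection, LAP linking, gap closing and track filters."""

import itertools

import numpy as np
import pytest

from spermwall import tracking as tr
from spermwall.trajectory import Spot, Trajectory, group_spots_by_frame

from conftest import make_traj


def spots_at(frame, coords):
    return [Spot(frame=frame, x=float(x), y=float(y)) for x, y in coords]


def bruteforce_matching(src, dst, gate):
    """Exhaustive gated matching minimising Σd² + gate²·(# unmatched spots)."""
    gate2 = gate * gate
    n, m = len(src), len(dst)
    best_cost, best_links = gate2 * (n + m), frozenset()
    for k in range(0, min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                d2s = [np.sum((np.asarray(src[r]) - np.asarray(dst[c])) ** 2)
                       for r, c in zip(rows, cols)]
                if any(d2 > gate2 for d2 in d2s):
                    continue
                cost = sum(d2s) + gate2 * ((n - k) + (m - k))
                if cost < best_cost - 1e-12:
                    best_cost = cost
                    best_links = frozenset(zip(rows, cols))
    return best_cost, best_links


def links_from_tracks(tracks):
    """Set of ((f, x1, y1), (f+1, x2, y2)) consecutive-frame links."""
    out = set()
    for t in tracks:
        for a, b in zip(t.spots, t.spots[1:]):
            if b.frame == a.frame + 1:
                out.add(((a.frame, a.x, a.y), (b.frame, b.x, b.y)))
    return out


class TestDetect:
    def test_blank_frame_empty(self):
        assert tr.detect_spots(np.zeros((64, 64)), 1.0) == []

    def test_constant_frame_with_otsu_empty(self):
        assert tr.detect_spots(np.full((64, 64), 7.0), 1.0) == []

    def test_single_blob_subpixel_centroid(self):
        yy, xx = np.mgrid[0:64, 0:64]
        img = 100.0 * np.exp(-((xx - 30.4) ** 2 + (yy - 21.7) ** 2) / (2 * 2.0 ** 2))
        spots = tr.detect_spots(img, 1.0)
        assert len(spots) == 1
        assert spots[0].x == pytest.approx(30.4, abs=0.5)
        assert spots[0].y == pytest.approx(21.7, abs=0.5)

    def test_single_pixel_component_fails_radius_gate(self):
        # area 1 px at 1 µm/px: radius sqrt(1/π) ≈ 0.564 µm <= 0.75 → discarded
        img = np.zeros((32, 32))
        img[16, 16] = 100.0
        cfg = tr.TrackingConfig(detect_sigma_um=0.2, detect_threshold=30.0)
        assert tr.detect_spots(img, 1.0, cfg) == []
        img[15:18, 15:18] = 100.0  # 9 px → radius 1.69 µm, kept
        spots = tr.detect_spots(img, 1.0, cfg)
        assert len(spots) == 1 and spots[0].radius > 0.75

    def test_empty_image_is_an_error(self):
        with pytest.raises(ValueError):
            tr.detect_spots(np.zeros((0, 0)), 1.0)


class TestLink:
    def test_within_gate_links(self):
        spots = {0: spots_at(0, [(0, 0)]), 1: spots_at(1, [(5, 0)])}
        tracks = tr.link_spots(spots)
        assert len(tracks) == 1 and len(tracks[0]) == 2

    def test_jump_beyond_gate_splits(self):
        spots = {0: spots_at(0, [(0, 0)]), 1: spots_at(1, [(15, 0)])}
        tracks = tr.link_spots(spots)
        assert sorted(len(t) for t in tracks) == [1, 1]

    def test_three_wellseparated_tracks_match_nn_oracle(self):
        rng = np.random.default_rng(0)
        anchors = np.array([[50.0, 50.0], [200.0, 60.0], [120.0, 220.0]])
        paths = {f: anchors + rng.normal(0, 1.0, anchors.shape) + f * 2.0
                 for f in range(20)}
        spots = {f: spots_at(f, paths[f]) for f in range(20)}
        tracks = tr.link_spots(spots)
        assert len(tracks) == 3
        # each track follows exactly one anchor (nearest-neighbour oracle)
        for t in tracks:
            start = np.array([t.spots[0].x, t.spots[0].y])
            anchor = np.argmin(np.hypot(*(paths[0] - start).T))
            for s in t.spots:
                assert np.argmin(np.hypot(*(paths[s.frame] - s.xy).T)) == anchor

    def test_assignment_equals_bruteforce_on_small_instances(self):
        """Optimal-matching oracle on random instances with <= 5 spots/frame."""
        rng = np.random.default_rng(123)
        cfg = tr.TrackingConfig()
        for _ in range(25):
            n_frames = int(rng.integers(2, 10))
            spots = {f: spots_at(f, rng.uniform(0, 60, (int(rng.integers(0, 6)), 2)))
                     for f in range(n_frames)}
            tracks = tr.link_spots(spots, cfg)
            got = links_from_tracks(tracks)
            expected = set()
            grouped = group_spots_by_frame(s for ss in spots.values() for s in ss)
            for f in range(n_frames - 1):
                src = [(s.x, s.y) for s in grouped.get(f, [])]
                dst = [(s.x, s.y) for s in grouped.get(f + 1, [])]
                _, links = bruteforce_matching(src, dst, cfg.max_link_um)
                for r, c in links:
                    expected.add(((f, *src[r]), (f + 1, *dst[c])))
            assert got == expected

    def test_spot_conservation_before_filtering(self):
        rng = np.random.default_rng(9)
        spots = {f: spots_at(f, rng.uniform(0, 100, (4, 2))) for f in range(8)}
        tracks = tr.link_spots(spots)
        emitted = [(s.frame, s.x, s.y) for t in tracks for s in t.spots]
        original = [(s.frame, s.x, s.y) for ss in spots.values() for s in ss]
        assert sorted(emitted) == sorted(original)

    def test_no_link_exceeds_gate(self):
        rng = np.random.default_rng(17)
        spots = {f: spots_at(f, rng.uniform(0, 40, (5, 2))) for f in range(10)}
        for t in tr.link_spots(spots):
            for a, b in zip(t.spots, t.spots[1:]):
                assert np.hypot(b.x - a.x, b.y - a.y) <= 11.0 + 1e-9


class TestCloseGaps:
    def seg(self, tid, frames, coords):
        return Trajectory(id=tid, spots=[
            Spot(frame=f, x=float(x), y=float(y))
            for f, (x, y) in zip(frames, coords)], source="tracked")

    def test_gap_of_two_frames_closed(self):
        a = self.seg("a", range(0, 11), [(i, 0) for i in range(11)])
        b = self.seg("b", range(12, 20), [(14 + i, 0) for i in range(8)])
        merged = tr.close_gaps([a, b])
        assert len(merged) == 1
        assert merged[0].frames.tolist() == list(range(0, 11)) + list(range(12, 20))

    def test_gap_of_four_frames_not_closed(self):
        a = self.seg("a", range(0, 11), [(i, 0) for i in range(11)])
        b = self.seg("b", range(14, 20), [(14 + i, 0) for i in range(6)])
        assert len(tr.close_gaps([a, b])) == 2

    def test_distance_gate_respected(self):
        a = self.seg("a", range(0, 5), [(i, 0) for i in range(5)])
        b = self.seg("b", range(6, 10), [(30 + i, 0) for i in range(4)])
        assert len(tr.close_gaps([a, b])) == 2

    def test_chain_of_three_segments(self):
        a = self.seg("a", range(0, 5), [(i, 0) for i in range(5)])
        b = self.seg("b", range(6, 10), [(6 + i, 0) for i in range(4)])
        c = self.seg("c", range(11, 15), [(12 + i, 0) for i in range(4)])
        merged = tr.close_gaps([a, b, c])
        assert len(merged) == 1
        assert len(merged[0]) == 13

    def test_no_closed_gap_exceeds_gates(self):
        rng = np.random.default_rng(31)
        spots = {f: spots_at(f, rng.uniform(0, 50, (3, 2))) for f in range(12)}
        closed = tr.close_gaps(tr.link_spots(spots))
        for t in closed:
            for a, b in zip(t.spots, t.spots[1:]):
                gap = b.frame - a.frame
                assert gap <= 2  # a link step (1) or a closed gap (<= 2 frames)
                if gap > 1:
                    assert np.hypot(b.x - a.x, b.y - a.y) <= 11.0 + 1e-9


class TestFilters:
    @pytest.mark.parametrize("n_spots,step,expect_kept,reason", [
        (6, 3.0, False, "min_spots"),          # > 6 spots required
        (10, 0.1, False, "min_displacement"),  # net displacement 0.9 <= 2.5 µm
        (10, 2.0, True, None),                 # passes both gates
        (7, 1.0, True, None),                  # boundary: 7 spots, 6 µm
    ])
    def test_gate_table(self, n_spots, step, expect_kept, reason):
        t = make_traj([(i * step, 0.0) for i in range(n_spots)])
        report = tr.filter_tracks([t])
        if expect_kept:
            assert [k.id for k in report.kept] == [t.id]
        else:
            assert report.kept == []
            assert report.rejected[0].reason == reason
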