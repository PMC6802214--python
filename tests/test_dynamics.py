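"""Overlap tracking, lifetime/size distributions and coverage."""
import numpy as np
import pytest

from fastrata import (
    ColonySpec,
    MovieSpec,
    coverage_fraction,
    generate_adhesion_movie,
    lifetime_distribution,
    max_size_distribution,
    summarize_dynamics,
    track_adhesions,
)
from fastrata.dynamics import Track, TrackSet


def blob_stack(n_frames, shape=(20, 20), spans=None):
    """spans: list of (label, (r0, r1, c0, c1), first_frame, last_frame)."""
    stack = np.zeros((n_frames, *shape), dtype=np.uint16)
    for lab, (r0, r1, c0, c1), f0, f1 in spans:
        for t in range(f0, f1 + 1):
            stack[t, r0:r1, c0:c1] = lab
    return stack


class TestTracking:
    def test_static_blob_single_track(self):
        stack = blob_stack(8, spans=[(1, (5, 8, 5, 8), 0, 7)])
        ts = track_adhesions(stack, pixel_um=1.0)
        assert len(ts.tracks) == 1
        assert ts.tracks[0].n_frames == 8

    def test_two_disjoint_blobs_two_tracks(self):
        stack = blob_stack(5, spans=[(1, (2, 4, 2, 4), 0, 4), (2, (12, 14, 12, 14), 0, 4)])
        assert len(track_adhesions(stack, pixel_um=1.0).tracks) == 2

    def test_gap_ends_track(self):
        # one-frame disappearance starts a new track (no gap closing)
        stack = blob_stack(5, spans=[(1, (5, 8, 5, 8), 0, 1), (1, (5, 8, 5, 8), 3, 4)])
        ts = track_adhesions(stack, pixel_um=1.0)
        assert sorted(t.n_frames for t in ts.tracks) == [2, 2]

    def test_relabeling_between_frames_keeps_track(self):
        stack = blob_stack(4, spans=[(1, (5, 8, 5, 8), 0, 1)])
        stack[2:, 5:8, 5:8] = 9  # same blob, new label
        ts = track_adhesions(stack, pixel_um=1.0)
        assert len(ts.tracks) == 1 and ts.tracks[0].n_frames == 4

    def test_split_keeps_identity_on_largest_fragment(self):
        stack = np.zeros((2, 20, 20), dtype=np.uint16)
        stack[0, 5:11, 5:11] = 1
        stack[1, 5:10, 5:11] = 2  # large fragment
        stack[1, 10:11, 5:11] = 3  # small fragment
        ts = track_adhesions(stack, pixel_um=1.0)
        lengths = sorted(t.n_frames for t in ts.tracks)
        assert lengths == [1, 2]  # continuation plus one new track

    def test_every_labeled_pixel_belongs_to_a_track(self):
        colony = ColonySpec(image_shape=(80, 80), pixel_um=0.5, n_edge_fa=4, n_centre_fa=6)
        stack, gt = generate_adhesion_movie(colony, MovieSpec(n_frames=15, seed=5))
        ts = track_adhesions(stack, pixel_um=0.5)
        for t in range(len(stack)):
            frame_area = (stack[t] > 0).sum() * 0.25
            tracked = sum(
                tr.areas_um2[t - tr.start_frame]
                for tr in ts.tracks if tr.start_frame <= t <= tr.end_frame
            )
            assert tracked == pytest.approx(frame_area)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            track_adhesions([np.zeros((5, 5)), np.zeros((6, 6))], pixel_um=1.0)


class TestLifetime:
    def track_set(self, lengths, interval=1.0, klass="edge"):
        tracks = [
            Track(track_id=i, start_frame=0, areas_um2=[1.0] * n, klass=klass)
            for i, n in enumerate(lengths)
        ]
        return TrackSet(tracks, frame_interval_min=interval, pixel_um=1.0)

    def test_lifetime_is_frames_times_interval(self):
        ts = self.track_set([5])
        assert ts.lifetimes_min()[0] == 5.0

    def test_frames_3_to_7_is_five_minutes(self):
        tr = Track(track_id=0, start_frame=3, areas_um2=[1.0] * 5)
        assert tr.end_frame == 7
        ts = TrackSet([tr], frame_interval_min=1.0, pixel_um=1.0)
        assert ts.lifetimes_min()[0] == 5.0

    def test_cap_at_105_minutes(self):
        ts = self.track_set([200])
        assert ts.lifetimes_min(cap_min=105)[0] == 105.0

    def test_capping_idempotent(self):
        ts = self.track_set([200, 50, 120])
        once = ts.lifetimes_min(cap_min=105)
        assert np.array_equal(np.minimum(once, 105), once)

    def test_frequencies_sum_to_one_per_class(self):
        tracks = self.track_set([5, 20, 200], klass="edge").tracks
        tracks += self.track_set([3, 7], klass="centre").tracks
        ts = TrackSet(tracks, frame_interval_min=1.0, pixel_um=1.0)
        dist = lifetime_distribution(ts)
        assert set(dist) == {"edge", "centre"}
        for d in dist.values():
            assert d.frequencies.sum() == pytest.approx(1.0)

    def test_max_size_distribution_normalized(self):
        ts = self.track_set([3, 4])
        ts.tracks[0].areas_um2 = [0.2, 1.4, 0.6]
        dist = max_size_distribution(ts)
        d = dist["edge"]
        assert d.frequencies.sum() == pytest.approx(1.0)

    def test_empty_track_set_yields_empty_distribution(self):
        ts = TrackSet([], frame_interval_min=1.0, pixel_um=1.0)
        assert lifetime_distribution(ts) == {}


class TestCoverage:
    def test_half_covered_edge(self):
        edge = np.zeros((10, 10), dtype=bool)
        edge[:, :4] = True
        centre = ~edge
        frame = np.zeros((10, 10), dtype=np.uint16)
        frame[:5, :4] = 1  # half the edge strip
        cov = coverage_fraction([frame], edge, centre)
        assert cov["edge"][0] == pytest.approx(50.0)

    def test_blank_frame_zero_both_classes(self):
        edge = np.zeros((8, 8), dtype=bool)
        edge[0] = True
        cov = coverage_fraction([np.zeros((8, 8), dtype=np.uint16)], edge, ~edge)
        assert cov["edge"][0] == 0.0 and cov["centre"][0] == 0.0

    def test_empty_mask_signalled(self):
        edge = np.zeros((8, 8), dtype=bool)
        centre = np.zeros((8, 8), dtype=bool)
        centre[2:6, 2:6] = True
        with pytest.warns(UserWarning, match="edge mask is empty"):
            cov = coverage_fraction([np.ones((8, 8), dtype=np.uint16)], edge, centre)
        assert np.isnan(cov["edge"][0])

    def test_overlapping_masks_rejected(self):
        m = np.ones((4, 4), dtype=bool)
        with pytest.raises(ValueError, match="disjoint"):
            coverage_fraction([np.zeros((4, 4))], m, m)


@pytest.fixture(scope="module")
def movie():
    colony = ColonySpec(image_shape=(128, 128), pixel_um=0.5, edge_strip_um=6.0,
                        n_edge_fa=5, n_centre_fa=8,
                        edge_area_model=(0.5, 2.0, 0.5),
                        centre_area_model=(0.3, 0.8, 0.6))
    return generate_adhesion_movie(colony, MovieSpec(n_frames=40, seed=17))


class TestSyntheticMovieRecovery:
    def test_ground_truth_tracks_recovered(self, movie):
        stack, gt = movie
        ts, _ = summarize_dynamics(stack, gt.edge_mask, gt.centre_mask, pixel_um=0.5)
        # match recovered tracks against ground truth by (birth, death)
        truth = {(r.birth_frame, r.death_frame) for r in gt.tracks.itertuples()}
        found = {(t.start_frame, t.end_frame) for t in ts.tracks}
        recovered = len(truth & found)
        assert recovered / len(truth) >= 0.95

    def test_edge_more_stable_than_centre(self, movie):
        stack, gt = movie
        ts, _ = summarize_dynamics(stack, gt.edge_mask, gt.centre_mask, pixel_um=0.5)
        edge_lt = ts.by_class("edge").lifetimes_min()
        centre_lt = ts.by_class("centre").lifetimes_min()
        assert np.median(edge_lt) > np.median(centre_lt)

    def test_coverage_matches_ground_truth_accounting(self, movie):
        stack, gt = movie
        _, summary = summarize_dynamics(stack, gt.edge_mask, gt.centre_mask, pixel_um=0.5)
        t = 10
        drawn = gt.frame_areas[gt.frame_areas["frame"] == t]
        edge_ids = set(gt.tracks[gt.tracks["klass"] == "edge"]["adhesion_id"])
        edge_px = drawn[drawn["adhesion_id"].isin(edge_ids)]["area_um2"].sum() / 0.25
        expected = 100.0 * edge_px / gt.edge_mask.sum()
        assert summary.coverage_pct["edge"][t] == pytest.approx(expected)
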