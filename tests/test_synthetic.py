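"""Ground-truth generator: layered localizations, area mixtures, movies."""
import numpy as np
import pandas as pd
import pytest
from scipy.signal import find_peaks

from fastrata import (
    ColonySpec,
    LayerSpec,
    MovieSpec,
    generate_adhesion_movie,
    generate_fa_areas,
    generate_layered_localizations,
    make_histogram,
)


class TestLayeredLocalizations:
    def test_determinism_and_seed_sensitivity(self):
        spec = LayerSpec.from_reference("paxillin", count=500)
        a = generate_layered_localizations(spec, seed=9)
        b = generate_layered_localizations(spec, seed=9)
        c = generate_layered_localizations(spec, seed=10)
        pd.testing.assert_frame_equal(a.data, b.data)
        assert not a.data["z_nm"].equals(c.data["z_nm"])

    def test_zero_count_gives_empty_table(self):
        spec = LayerSpec("p", [(100.0, 15.0, 1.0)], count=0)
        assert len(generate_layered_localizations(spec, seed=1)) == 0

    def test_single_component_moments(self):
        # sample-moment oracle: mean within 3*sigma/sqrt(n), SD within 5%
        spec = LayerSpec("g", [(100.0, 15.0, 1.0)], count=20000)
        z = generate_layered_localizations(spec, seed=4).z
        assert abs(z.mean() - 100.0) < 3 * 15.0 / np.sqrt(20000)
        assert abs(z.std() - 15.0) / 15.0 < 0.05

    @pytest.mark.parametrize("protein", ["paxillin", "talin_c", "kank1_distal"])
    def test_reference_layer_moments(self, protein):
        spec = LayerSpec.from_reference(protein, count=20000)
        mu, sd, _ = spec.components[0]
        z = generate_layered_localizations(spec, seed=11).z
        assert abs(z.mean() - mu) < 4 * sd / np.sqrt(20000)
        assert abs(z.std() - sd) / sd < 0.05

    def test_actin_histogram_is_bimodal_with_trough(self):
        # the two actin layers are separated by a clear low-density gap
        spec = LayerSpec.from_reference("actin", count=20000)
        hist = make_histogram(generate_layered_localizations(spec, seed=2).z, bin_width=1.0)
        smooth = np.convolve(hist.counts, np.ones(5) / 5, mode="same")
        peaks, props = find_peaks(smooth, prominence=smooth.max() * 0.2)
        assert len(peaks) == 2
        trough = smooth[peaks[0]: peaks[1] + 1].min()
        assert trough < 0.5 * smooth[peaks].min()

    def test_two_component_weight_split(self):
        # far-separated layers let us count component draws directly
        spec = LayerSpec("w", [(0.0, 1.0, 0.3), (1000.0, 1.0, 0.7)], count=50000)
        z = generate_layered_localizations(spec, seed=3).z
        frac_low = np.mean(z < 500)
        assert abs(frac_low - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 50000)

    def test_cup_raises_z_with_radius(self):
        spec = LayerSpec("v", [(80.0, 5.0, 1.0)], lateral="cup",
                         cup_coeff=1e-4, radius_nm=1000, count=10000)
        t = generate_layered_localizations(spec, seed=5)
        r = np.hypot(t.data["x_nm"], t.data["y_nm"])
        inner = t.z[r < 300].mean()
        outer = t.z[r > 700].mean()
        assert outer > inner + 20  # k*r^2 contrast

    def test_edge_ring_confined_to_annulus(self):
        spec = LayerSpec("t", [(70.0, 10.0, 1.0)], lateral="edge_ring",
                         radius_nm=900, rim_width_nm=150, count=5000)
        t = generate_layered_localizations(spec, seed=6)
        r = np.hypot(t.data["x_nm"], t.data["y_nm"])
        assert r.min() >= 750 - 1e-9 and r.max() <= 900 + 1e-9

    def test_background_fraction_spreads_z(self):
        spec = LayerSpec("p", [(50.0, 2.0, 1.0)], count=20000,
                         background_fraction=0.2, background_z_range=(0, 300))
        z = generate_layered_localizations(spec, seed=7).z
        frac_above = np.mean(z > 100)  # only background reaches up there
        assert 0.1 < frac_above < 0.18  # ~ 0.2 * (200/300)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"components": [(100.0, 15.0, 0.5)]},  # weights don't sum to 1
            {"components": [(100.0, -1.0, 1.0)]},  # negative width
            {"components": [(100.0, 15.0, 1.0)], "count": -1},
            {"components": [(100.0, 15.0, 1.0)], "background_fraction": 1.0},
            {"components": [(100.0, 15.0, 1.0)], "lateral": "pyramid"},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LayerSpec("bad", **kwargs)


class TestFaAreas:
    def test_pure_exponential_when_w_is_one(self):
        x = generate_fa_areas(1.8, 4.2, 1.0, 50000, seed=1)
        assert abs(x.mean() - 1.8) < 4 * 1.8 / np.sqrt(50000)

    def test_large_component_when_w_is_zero(self):
        x = generate_fa_areas(0.8, 4.2, 0.0, 50000, seed=2)
        assert abs(x.mean() - 4.2) < 4 * 4.2 / np.sqrt(50000)

    @pytest.mark.parametrize("a1,a2,w", [(0.5, 2.0, 0.3), (0.8, 4.2, 0.6)])
    def test_mixture_mean_matches_analytic(self, a1, a2, w):
        x = generate_fa_areas(a1, a2, w, 100000, seed=3)
        expected = w * a1 + (1 - w) * a2
        sd = np.sqrt(w * 2 * a1**2 + (1 - w) * 2 * a2**2)  # bound on mixture SD
        assert abs(x.mean() - expected) < 4 * sd / np.sqrt(100000)

    def test_ordering_convention_enforced(self):
        with pytest.raises(ValueError):
            generate_fa_areas(4.2, 0.8, 0.5, 10, seed=0)


@pytest.fixture(scope="module")
def small_movie():
    colony = ColonySpec(image_shape=(96, 96), pixel_um=0.5, edge_strip_um=5.0,
                        n_edge_fa=4, n_centre_fa=8)
    movie = MovieSpec(n_frames=30, seed=21)
    return generate_adhesion_movie(colony, movie)


class TestMovie:
    def test_edge_adhesions_span_movie(self, small_movie):
        _, gt = small_movie
        edge = gt.tracks[gt.tracks["klass"] == "edge"]
        assert (edge["birth_frame"] == 0).all()
        assert (edge["death_frame"] == 29).all()

    def test_labels_stable_and_unique_per_pixel(self, small_movie):
        stack, gt = small_movie
        ids = set(gt.tracks["adhesion_id"])
        for frame in stack:
            present = set(np.unique(frame)) - {0}
            assert present <= ids

    def test_frame_areas_match_pixel_counts(self, small_movie):
        stack, gt = small_movie
        for _, row in gt.frame_areas.sample(20, random_state=0).iterrows():
            n_px = int((stack[int(row["frame"])] == row["adhesion_id"]).sum())
            assert n_px * 0.25 == pytest.approx(row["area_um2"])

    def test_coverage_accounting_against_ground_truth(self, small_movie):
        stack, gt = small_movie
        t = 5
        drawn = gt.frame_areas[gt.frame_areas["frame"] == t]
        edge_ids = set(gt.tracks[gt.tracks["klass"] == "edge"]["adhesion_id"])
        edge_px = sum(
            row["area_um2"] / 0.25
            for _, row in drawn.iterrows() if row["adhesion_id"] in edge_ids
        )
        direct = ((stack[t] > 0) & gt.edge_mask).sum()
        assert edge_px == pytest.approx(direct)

    def test_bit_reproducible(self):
        colony = ColonySpec(image_shape=(64, 64), pixel_um=0.5, n_edge_fa=3, n_centre_fa=5)
        s1, _ = generate_adhesion_movie(colony, MovieSpec(n_frames=10, seed=8))
        s2, _ = generate_adhesion_movie(colony, MovieSpec(n_frames=10, seed=8))
        assert np.array_equal(s1, s2)

    def test_oversized_adhesion_rejected(self):
        colony = ColonySpec(image_shape=(32, 32), pixel_um=0.1, n_edge_fa=2, n_centre_fa=0,
                            edge_area_model=(5e4, 1e5, 0.5), edge_strip_um=1.0)
        with pytest.raises(ValueError, match="exceeds colony area"):
            generate_adhesion_movie(colony, MovieSpec(n_frames=2, seed=1))
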