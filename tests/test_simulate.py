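"""Synthetic-scene generator: geometry, determinism, conservation, noise."""

import numpy as np
import pytest
from scipy.stats import norm

from mtllps import (
    FilamentPath,
    GroundTruth,
    PlantedCompartment,
    SimulationSpec,
    make_coloc_scene,
    make_network,
    make_profile_pair,
    render_scene,
    sample_profile,
)


class TestNetwork:
    def test_zero_paths_gives_empty_network(self):
        spec = SimulationSpec(n_paths=0)
        assert make_network(spec) == []

    def test_straight_segment_arc_length(self):
        # 100 px at 30 nm/px = 3 um
        p = FilamentPath(path_id=0, vertices=[(10, 10), (10, 110)], pixel_size_nm=30)
        assert p.length_um == pytest.approx(3.0)

    def test_random_walk_total_length_within_one_percent(self):
        spec = SimulationSpec(n_paths=25, total_length_um=300.0, seed=4)
        paths = make_network(spec)
        # oracle: direct summation of polyline segment lengths
        total = sum(
            np.linalg.norm(np.diff(p.vertices, axis=0), axis=1).sum() * 30 / 1000
            for p in paths
        )
        assert abs(total - 300.0) / 300.0 < 0.01

    def test_paths_stay_inside_image(self):
        spec = SimulationSpec(n_paths=12, seed=9)
        for p in make_network(spec):
            p.check_in_bounds(spec.image_shape)
            assert np.all(np.diff(p.arc_um) > 0)

    def test_network_reproducible_under_seed(self):
        spec = SimulationSpec(n_paths=5, seed=123)
        a = make_network(spec)
        b = make_network(spec)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.vertices, pb.vertices)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SimulationSpec(n_paths=-1)
        with pytest.raises(ValueError):
            SimulationSpec(image_shape=(16, 16), path_model="straight",
                           path_length_um=50.0)
        with pytest.raises(ValueError):
            SimulationSpec(base_intensity_ch1=0.0)
        with pytest.raises(ValueError):
            SimulationSpec(pixel_size_nm=-1.0)


class TestRenderScene:
    def test_uniform_decoration_gives_constant_ratio_on_filament(self):
        spec = SimulationSpec(
            n_paths=3, seed=2, noise_model="none", background_level=0.0,
            base_intensity_ch1=1000.0, base_intensity_ch2=500.0,
        )
        paths = make_network(spec)
        img, _ = render_scene(paths, [], spec)
        on = img.ch2 > 0.05 * img.ch2.max()
        ratio = img.ch1[on] / img.ch2[on]
        np.testing.assert_allclose(ratio, 2.0, rtol=1e-9)

    def test_conservation_without_psf_and_noise(self):
        # on-filament intensity of an unplanted channel equals base exactly
        spec = SimulationSpec(
            n_paths=2, seed=5, noise_model="none", background_level=0.0,
            psf_sigma_nm=0.0,
        )
        paths = make_network(spec)
        img, _ = render_scene(paths, [], spec)
        on = img.ch1 > 0
        assert np.all(img.ch1[on] == spec.base_intensity_ch1)
        assert np.all(img.ch2[on] == spec.base_intensity_ch2)

    def test_planted_fold_matches_boxcar_psf_convolution_oracle(self):
        # straight filament, one enrich_ch1 compartment: the on-path ratio
        # must follow the 1D convolution of a boxcar with the Gaussian PSF
        spec = SimulationSpec(
            image_shape=(64, 600), n_paths=1, path_model="straight",
            path_length_um=15.0, seed=0, noise_model="none",
            background_level=0.0, psf_sigma_nm=90.0,
        )
        path = FilamentPath(0, [(32.0, 50.0), (32.0, 550.0)], pixel_size_nm=30.0)
        a_um, b_um, fold = 6.0, 9.0, 2.0
        comp = PlantedCompartment(0, a_um, b_um, "enrich_ch1", fold)
        img, _ = render_scene([path], [comp], spec)
        prof = sample_profile(img, path)
        ratio = prof.i_rbp1 / prof.i_rbp2
        s = prof.positions_um
        sigma_um = spec.psf_sigma_nm / 1000.0
        expected = 1.0 + (fold - 1.0) * (
            norm.cdf((s - a_um) / sigma_um) - norm.cdf((s - b_um) / sigma_um)
        )
        # rasterization quantizes the boxcar edge to the pixel grid: up to a
        # half-pixel (15 nm) shift, i.e. (fold-1)*pdf(0)/sigma * 15 nm ~ 0.07
        np.testing.assert_allclose(ratio, expected, atol=0.08)
        assert ratio.max() == pytest.approx(fold, rel=0.02)

    def test_seeded_render_is_bit_identical(self):
        spec = SimulationSpec(n_paths=4, seed=7)
        paths = make_network(spec)
        planted = [PlantedCompartment(0, 1.0, 3.0, "enrich_ch1", 2.0)]
        img1, _ = render_scene(paths, planted, spec)
        img2, _ = render_scene(paths, planted, spec)
        np.testing.assert_array_equal(img1.ch1, img2.ch1)
        np.testing.assert_array_equal(img1.ch2, img2.ch2)

    def test_planted_segment_outside_path_raises(self):
        spec = SimulationSpec(n_paths=1, path_length_um=5.0, seed=1)
        paths = make_network(spec)
        bad = [PlantedCompartment(0, 4.0, 9.0, "enrich_ch1", 2.0)]
        with pytest.raises(ValueError, match="exceeds path"):
            render_scene(paths, bad, spec)
        with pytest.raises(ValueError, match="unknown path"):
            render_scene(paths, [PlantedCompartment(3, 1.0, 2.0, "enrich_ch1", 2.0)], spec)

    def test_overlapping_planted_segments_rejected(self):
        spec = SimulationSpec(n_paths=1, seed=1)
        paths = make_network(spec)
        bad = [
            PlantedCompartment(0, 1.0, 3.0, "enrich_ch1", 2.0),
            PlantedCompartment(0, 2.0, 4.0, "enrich_ch2", 2.0),
        ]
        with pytest.raises(ValueError, match="overlap"):
            render_scene(paths, bad, spec)


class TestProfilePairGenerator:
    def test_noiseless_unplanted_profiles_are_constant(self):
        p, _ = make_profile_pair([], 10.0, base1=100.0, base2=50.0)
        assert np.all(p.i_rbp1 == 100.0)
        assert np.all(p.i_rbp2 == 50.0)

    def test_fold_applies_to_exactly_the_covered_samples(self):
        c = PlantedCompartment(0, 2.0, 3.0, "enrich_ch1", 1.5)
        p, _ = make_profile_pair([c], 10.0, step_um=0.03, base1=100.0)
        inside = (p.positions_um >= 2.0) & (p.positions_um < 3.0)
        assert np.all(p.i_rbp1[inside] == 150.0)
        assert np.all(p.i_rbp1[~inside] == 100.0)
        assert np.all(p.i_rbp2 == 1000.0)

    @pytest.mark.parametrize("mode,f1,f2", [
        ("enrich_ch1", 2.0, 1.0),
        ("deplete_ch1", 0.5, 1.0),
        ("enrich_ch2", 1.0, 2.0),
        ("deplete_ch2", 1.0, 0.5),
    ])
    def test_mode_semantics(self, mode, f1, f2):
        c = PlantedCompartment(0, 1.0, 2.0, mode, 2.0)
        assert c.factors() == (f1, f2)

    def test_off_compartment_ratio_cv_matches_lognormal_oracle(self):
        # ratio of two independent multiplicative-noise channels: CV in
        # [0.03, 0.06] for 3% per-channel noise (lognormal ratio oracle)
        p, _ = make_profile_pair([], 300.0, noise_sd_frac=0.03, seed=3)
        assert len(p) == 10_000
        ratio = p.i_rbp1 / p.i_rbp2
        cv = ratio.std() / ratio.mean()
        assert 0.03 < cv < 0.06

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            make_profile_pair([], 10.0, noise_sd_frac=-0.1)

    def test_profile_must_cover_planted_extent(self):
        c = PlantedCompartment(0, 2.0, 12.0, "enrich_ch1", 2.0)
        with pytest.raises(ValueError):
            make_profile_pair([c], 10.0)


class TestColocScene:
    @pytest.mark.parametrize("co_fraction", [0.0, 0.5, 1.0])
    def test_mask_overlap_tracks_co_fraction(self, co_fraction):
        spec = SimulationSpec(
            n_paths=4, path_length_um=8.0, seed=17, noise_model="none",
            background_level=0.0,
        )
        img, gt = make_coloc_scene(co_fraction, spec)
        assert gt.true_coloc_fraction == pytest.approx(co_fraction)
        # moderate threshold: near filament crossings the PSF-blurred
        # contributions of the *other* channel's paths shift borderline
        # pixels, so a high threshold undercounts shared support
        m1 = img.ch1 > 0.3 * img.ch1.max()
        m2 = img.ch2 > 0.3 * img.ch2.max()
        overlap = (m1 & m2).sum() / m2.sum()
        assert overlap == pytest.approx(co_fraction, abs=0.05)

    def test_full_cooccupancy_shares_support(self):
        spec = SimulationSpec(n_paths=3, seed=8, noise_model="none",
                              background_level=0.0)
        img, _ = make_coloc_scene(1.0, spec)
        np.testing.assert_array_equal(img.ch1 > 0, img.ch2 > 0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_coloc_scene(1.5, SimulationSpec())


class TestGroundTruthSerialization:
    def test_json_round_trip(self, tmp_path):
        spec = SimulationSpec(n_paths=3, seed=6)
        paths = make_network(spec)
        planted = [PlantedCompartment(1, 0.5, 2.5, "mixed", 2.0, fold2=0.5)]
        gt = GroundTruth(spec=spec, paths=paths, planted=planted,
                         true_coloc_fraction=0.5)
        f = tmp_path / "gt.json"
        gt.write_json(f)
        back = GroundTruth.read_json(f)
        assert back.to_dict() == gt.to_dict()
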