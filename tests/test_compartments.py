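"""Ratio profiles, compartment detection, attribution and summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtllps import (
    PlantedCompartment,
    ProfilePair,
    analyze_cell,
    attribute_compartment,
    compare_groups,
    detect_compartments,
    make_profile_pair,
    ratio_profile,
    summarize,
)
from mtllps.compartments import (
    ENRICHMENT_OF_DOMINANT,
    EXCLUSION_OF_OTHER,
    Compartment,
    RatioProfile,
)
from mtllps.benchmarks import bruteforce_segments, _random_profile_pair


def _pair(i1, i2, step=0.03):
    i1 = np.asarray(i1, dtype=float)
    pos = (np.arange(len(i1)) + 0.5) * step
    return ProfilePair(path_id=0, positions_um=pos, i_rbp1=i1,
                       i_rbp2=np.asarray(i2, dtype=float), step_um=step)


def _rp_from_n(n, step=0.03):
    n = np.asarray(n, dtype=float)
    pos = (np.arange(len(n)) + 0.5) * step
    return RatioProfile(positions_um=pos, r=n, n=n, epsilon1=0.0, epsilon2=0.0,
                        step_um=step, path_id=0, mean_i1=1.0, mean_i2=1.0)


class TestRatioProfile:
    def test_identical_channels_give_unit_ratio(self):
        rng = np.random.default_rng(0)
        i = rng.uniform(10, 100, 500)
        rp = ratio_profile(_pair(i, i.copy()))
        np.testing.assert_allclose(rp.n, 1.0, rtol=1e-12)

    def test_two_level_profile_closed_form(self):
        # I1 doubled on half the samples: r in {2, 1}, geometric mean sqrt(2),
        # so n takes exactly the values sqrt(2) and 1/sqrt(2)
        i1 = np.array([2.0] * 50 + [1.0] * 50)
        i2 = np.ones(100)
        rp = ratio_profile(_pair(i1, i2), epsilon_frac=0.0)
        np.testing.assert_allclose(np.unique(rp.n),
                                   [2 ** -0.5, 2 ** 0.5], rtol=1e-12)
        assert np.exp(np.mean(np.log(rp.n))) == pytest.approx(1.0, abs=1e-12)

    def test_epsilon_guards_isolated_zero(self):
        i2 = np.ones(100)
        i2[40] = 0.0
        rp = ratio_profile(_pair(np.ones(100), i2), epsilon_frac=0.01)
        assert np.all(np.isfinite(rp.n))

    def test_zero_channel_without_epsilon_reports_position(self):
        i2 = np.ones(100)
        i2[40] = 0.0
        i2 -= i2  # all-zero denominator
        with pytest.raises(ZeroDivisionError, match="sample 0"):
            ratio_profile(_pair(np.ones(100), i2), epsilon_frac=0.0)


class TestDetection:
    def test_same_protein_profile_yields_no_compartment(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(50, 150, 2000)  # shared structure cancels in ratio
        rp = ratio_profile(_pair(base, base.copy()))
        assert detect_compartments(rp) == []

    def test_boxcar_deviation_length_and_enrichment(self):
        # 1 um stretch at ratio 1.25 on a long baseline: one RBP1 compartment
        # of L = 1 um (+- one step) and enrichment just under 25% (the
        # geometric-mean normalization sees 1% of samples elevated)
        c = PlantedCompartment(0, 50.0, 51.0, "enrich_ch1", 1.25)
        p, _ = make_profile_pair([c], 100.0, step_um=0.03)
        rp = ratio_profile(p)
        comps = detect_compartments(rp, smoothing_window=1)
        assert len(comps) == 1
        comp = comps[0]
        assert comp.dominant_channel == "RBP1"
        assert comp.length_um == pytest.approx(1.0, abs=0.031)
        assert comp.enrichment_pct == pytest.approx(25.0, abs=1.0)
        assert comp.start_um <= comp.argmax_um <= comp.end_um

    def test_threshold_is_strict(self):
        # deviations of exactly +-20% must not trigger a detection
        n = np.ones(200)
        n[50:80] = 1.2
        n[120:150] = 1.0 / 1.2
        assert detect_compartments(_rp_from_n(n), smoothing_window=1) == []
        n[50:80] = 1.2000001
        got = detect_compartments(_rp_from_n(n), smoothing_window=1)
        assert len(got) == 1 and got[0].dominant_channel == "RBP1"

    def test_short_runs_discarded(self):
        n = np.ones(200)
        n[50:54] = 1.5  # 4 samples < min_run_samples=5
        assert detect_compartments(_rp_from_n(n), smoothing_window=1) == []
        n[50:55] = 1.5
        assert len(detect_compartments(_rp_from_n(n), smoothing_window=1)) == 1

    @pytest.mark.parametrize("window", [1, 5])
    def test_matches_bruteforce_maximal_run_scan(self, window):
        rng = np.random.default_rng(7)
        step = 0.03
        for _ in range(200):
            logn = rng.normal(0, 0.12, 250)
            for _ in range(rng.integers(0, 3)):
                a = int(rng.integers(0, 200))
                logn[a:a + int(rng.integers(5, 50))] += rng.uniform(-0.5, 0.5)
            n = np.exp(logn)
            got = [
                (c.dominant_channel,
                 int(round((c.start_um + step / 2) / step - 0.5)),
                 int(round((c.end_um - step / 2) / step - 0.5)))
                for c in detect_compartments(_rp_from_n(n, step),
                                             smoothing_window=window)
            ]
            assert got == bruteforce_segments(n, 0.20, 5, window)

    def test_bad_parameters_rejected(self):
        rp = _rp_from_n(np.ones(50))
        with pytest.raises(ValueError):
            detect_compartments(rp, threshold=0.0)
        with pytest.raises(ValueError):
            detect_compartments(rp, min_run_samples=0)


class TestInvariances:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_channel_swap_maps_compartments_exactly(self, seed):
        rng = np.random.default_rng(seed)
        p = _random_profile_pair(rng, 0)
        swapped = ProfilePair(path_id=0, positions_um=p.positions_um,
                              i_rbp1=p.i_rbp2.copy(), i_rbp2=p.i_rbp1.copy(),
                              step_um=p.step_um)
        a = detect_compartments(ratio_profile(p))
        b = detect_compartments(ratio_profile(swapped))
        flip = {"RBP1": "RBP2", "RBP2": "RBP1"}
        assert [(c.start_um, c.end_um, flip[c.dominant_channel]) for c in a] == [
            (c.start_um, c.end_um, c.dominant_channel) for c in b
        ]
        np.testing.assert_allclose(
            [c.enrichment_pct for c in a], [c.enrichment_pct for c in b], rtol=1e-9
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        p = _random_profile_pair(rng, 0)
        scaled = ProfilePair(path_id=0, positions_um=p.positions_um,
                             i_rbp1=3.7 * p.i_rbp1, i_rbp2=0.21 * p.i_rbp2,
                             step_um=p.step_um)
        a = detect_compartments(ratio_profile(p))
        b = detect_compartments(ratio_profile(scaled))
        assert [(c.start_um, c.end_um, c.dominant_channel) for c in a] == [
            (c.start_um, c.end_um, c.dominant_channel) for c in b
        ]
        np.testing.assert_allclose(
            [c.enrichment_pct for c in a], [c.enrichment_pct for c in b], rtol=1e-9
        )


class TestAttribution:
    def test_dominant_channel_above_its_mean_is_enrichment(self):
        # at the argmax I1 = 2 x mean(I1) while I2 sits at its mean
        n = 100
        x = 198.0 / 98.0  # solves x = 2 * mean for 99 unit samples + x
        i1 = np.ones(n)
        i1[50] = x
        p = _pair(i1, np.ones(n))
        c = Compartment(0, "RBP1", 1.4, 1.6, 100.0, argmax_um=p.positions_um[50])
        assert attribute_compartment(c, p, epsilon_frac=0.0) == ENRICHMENT_OF_DOMINANT

    def test_other_channel_below_its_mean_is_exclusion(self):
        # at the argmax I2 = 0.5 x mean(I2) while I1 sits at its mean
        n = 100
        y = 49.5 / 99.5
        i2 = np.ones(n)
        i2[50] = y
        p = _pair(np.ones(n), i2)
        c = Compartment(0, "RBP1", 1.4, 1.6, 100.0, argmax_um=p.positions_um[50])
        assert attribute_compartment(c, p, epsilon_frac=0.0) == EXCLUSION_OF_OTHER

    def test_classification_equals_log_deviation_formula(self):
        rng = np.random.default_rng(11)
        for k in range(30):
            p = _random_profile_pair(rng, k)
            rp = ratio_profile(p)
            for c in detect_compartments(rp):
                got = attribute_compartment(c, p, rp=rp)
                # independent re-evaluation of the discriminant
                i = int(np.argmin(np.abs(p.positions_um - c.argmax_um)))
                v = np.log((p.i_rbp1[i] + rp.epsilon1) / (np.mean(p.i_rbp1) + rp.epsilon1)) \
                    + np.log((p.i_rbp2[i] + rp.epsilon2) / (np.mean(p.i_rbp2) + rp.epsilon2))
                want = ENRICHMENT_OF_DOMINANT if v > 0 else EXCLUSION_OF_OTHER
                assert got == want

    def test_zero_intensity_without_epsilon_raises(self):
        i2 = np.zeros(50)
        p = ProfilePair(path_id=0, positions_um=(np.arange(50) + 0.5) * 0.03,
                        i_rbp1=np.ones(50), i_rbp2=i2, step_um=0.03)
        c = Compartment(0, "RBP1", 0.5, 1.0, 50.0, argmax_um=0.75)
        with pytest.raises(ZeroDivisionError):
            attribute_compartment(c, p, epsilon_frac=0.0)


class TestSummaries:
    def _cell_with(self, folds, seed=0):
        profiles = []
        for i, f in enumerate(folds):
            c = PlantedCompartment(i, 29.0, 31.0, "enrich_ch1", f)
            p, _ = make_profile_pair([c], 200.0, seed=seed + i, path_id=i)
            profiles.append(p)
        return analyze_cell(f"cell{seed}", profiles)

    def test_mean_length_of_two_compartments(self):
        cell = self._cell_with([2.0, 2.0])
        s = summarize([cell])
        assert s["n_compartments"] == 2
        assert s["length_um"]["mean"] == pytest.approx(2.0, abs=0.2)

    def test_pure_enrichment_has_zero_exclusion_fraction(self):
        cell = self._cell_with([2.0, 3.0])
        s = summarize([cell])
        assert s["attribution_fraction_exclusion"] == 0.0

    def test_planted_fold_grid_recovered_as_bimodal_enrichment(self):
        # folds {1.3, 2.0} on noiseless profiles: enrichment near {30, 100}
        cell = self._cell_with([1.3, 2.0, 1.3, 2.0])
        e = sorted(c.enrichment_pct for c in cell.compartments)
        assert len(e) == 4
        np.testing.assert_allclose(e[:2], 30.0, atol=3.0)
        np.testing.assert_allclose(e[2:], 100.0, atol=3.0)

    def test_qc_flag_below_half_millimeter(self):
        p, _ = make_profile_pair([], 100.0)
        cell = analyze_cell("short", [p])
        assert not cell.qc_pass
        assert not summarize([cell])["qc_all_cells_pass"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestGroupComparison:
    def _cells(self, enrich_shift, n=10, seed=0):
        cells = []
        rng = np.random.default_rng(seed)
        for i in range(n):
            fold = 1.6 + enrich_shift + 0.02 * rng.standard_normal()
            c = PlantedCompartment(0, 29.0, 31.0, "enrich_ch1", float(fold))
            p, _ = make_profile_pair([c], 100.0, seed=int(rng.integers(1 << 30)))
            cells.append(analyze_cell(f"g{seed}_{i}", [p]))
        return cells

    def test_identical_groups_not_significant(self):
        a = self._cells(0.0, seed=1)
        rep = compare_groups(a, a)
        assert rep["p"] == pytest.approx(1.0, abs=1e-9)
        assert rep["t"] == pytest.approx(0.0, abs=1e-9)

    def test_strongly_shifted_groups_significant(self):
        a = self._cells(0.0, seed=1)
        b = self._cells(0.6, seed=2)  # shift >> within-group spread
        rep = compare_groups(a, b)
        assert rep["p"] < 0.01
        assert rep["df"] == len(a) + len(b) - 2

    def test_single_cell_group_rejected(self):
        a = self._cells(0.0, n=1, seed=1)
        b = self._cells(0.0, n=5, seed=2)
        with pytest.raises(ValueError):
            compare_groups(a, b)

    def test_degenerate_variance_reported_not_crashed(self):
        a = self._cells(0.0, n=3, seed=1)
        # duplicate cells -> zero variance in both groups
        rep = compare_groups([a[0], a[0]], [a[0], a[0]])
        assert rep["degenerate_variance"] or rep["p"] is not None
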