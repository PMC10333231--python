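"""Ground-truth generator: outcome spectra, dye dilution, readout simulators."""

import math

import numpy as np
import pytest

from famred import popgen
from famred.popgen import (
    ConfigurationError,
    FlowChannelModel,
    Outcome,
    OutcomeProfile,
    simulate_cnv_baf_track,
    simulate_flow_sample,
    simulate_population,
    simulate_qpcr_panel,
    sort_by_tracking,
)


class TestOutcomeProfile:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ConfigurationError, match="sum"):
            OutcomeProfile(p_unedited=0.5, p_indel_only=0.4, p_cl_loh=0.2)

    def test_rejects_out_of_range_probability(self):
        with pytest.raises(ConfigurationError):
            OutcomeProfile(p_unedited=1.2, p_indel_only=-0.2)

    def test_rejects_nonpositive_fitness(self):
        with pytest.raises(ConfigurationError, match="fitness"):
            OutcomeProfile(p_unedited=1.0, p_indel_only=0.0, fitness_loh=0.0)

    def test_from_loh_total_composition(self):
        p = OutcomeProfile.from_loh_total(0.1, cl_share=0.36, dup_share=0.46)
        assert p.p_loh_total == pytest.approx(0.1, abs=1e-15)
        assert p.p_cl_loh == pytest.approx(0.036)
        assert p.p_cn_loh_dup == pytest.approx(0.064 * 0.46)


class TestSimulatePopulation:
    def test_no_loh_outcomes_means_all_reporters_functional(self):
        profile = OutcomeProfile(p_unedited=0.4, p_indel_only=0.6)
        pop = simulate_population(profile, 1000, seed=0)
        assert pop.cells["reporter_functional"].all()

    def test_forced_cn_loh_with_certain_targeting(self):
        profile = OutcomeProfile(p_unedited=0.0, p_indel_only=0.0, p_cn_loh=1.0)
        pop = simulate_population(profile, 100, seed=0, homolog_targeting=1.0)
        assert len(pop) == 100
        assert not pop.cells["reporter_functional"].any()

    def test_detectable_fraction_is_half_of_total_loh(self):
        # binomial oracle: with unbiased homolog targeting the detectable
        # fraction is p_loh / 2
        profile = OutcomeProfile.from_loh_total(0.002)
        n = 1_000_000
        pop = simulate_population(profile, n, seed=7, homolog_targeting=0.5)
        expected = 0.001
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(pop.detectable_loh_fraction() - expected) <= 3 * se

    @pytest.mark.parametrize("seed", range(10))
    def test_outcome_fraction_recovery(self, seed):
        profile = OutcomeProfile(
            p_unedited=0.3, p_indel_only=0.5, p_cl_loh=0.05, p_cn_loh=0.1,
            p_cn_loh_dup=0.05,
        )
        n = 100_000
        pop = simulate_population(profile, n, seed=seed)
        fractions = pop.outcome_fractions()
        for name, p in zip(
            [o.value for o in Outcome], profile.probabilities().values()
        ):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(fractions[name] - p) <= 3 * se, name

    def test_dye_dilution_halves_per_division_without_noise(self):
        profile = OutcomeProfile(p_unedited=1.0, p_indel_only=0.0)
        pop = simulate_population(
            profile, 5000, seed=3, mean_divisions=3.0, initial_intensity=1e4,
            intensity_cv=0.0,
        )
        log2i = np.log2(pop.cells["tracking_intensity"])
        expected = np.log2(1e4) - pop.cells["divisions"]
        assert np.allclose(log2i, expected)

    def test_reproducible_given_seed(self, wt_profile):
        a = simulate_population(wt_profile, 10_000, seed=42)
        b = simulate_population(wt_profile, 10_000, seed=42)
        assert a.cells.equals(b.cells)

    def test_invalid_size_rejected(self, wt_profile):
        with pytest.raises(ConfigurationError):
            simulate_population(wt_profile, 0, seed=0)


class TestSimulateFlowSample:
    def test_all_unedited_no_background_gives_zero_positives(
        self, unedited_profile, clean_model
    ):
        from famred import flow

        pop = simulate_population(unedited_profile, 20_000, seed=0)
        sample = simulate_flow_sample(pop, clean_model, seed=1)
        gate = flow.GateSpec(reporter_threshold=10**3.2, control_threshold=10**3.2)
        assert gate.positive_count(sample) == 0

    def test_switched_fraction_recovered(self, clean_model):
        from famred import flow

        profile = OutcomeProfile.from_loh_total(0.1)
        n = 100_000
        pop = simulate_population(profile, n, seed=5)
        sample = simulate_flow_sample(pop, clean_model, seed=6)
        gate = flow.GateSpec(reporter_threshold=10**3.2, control_threshold=10**3.2)
        p = pop.detectable_loh_fraction()
        se = math.sqrt(p * (1 - p) / n)
        assert abs(gate.positive_fraction(sample) - p) <= 3 * se

    def test_autofluorescent_events_excluded_by_control_channel(self, unedited_profile):
        from famred import flow

        model = FlowChannelModel(autofluorescence_rate=0.01, background_switch_rate=0.0)
        pop = simulate_population(unedited_profile, 50_000, seed=2)
        sample = simulate_flow_sample(pop, model, seed=3)
        gate = flow.GateSpec(reporter_threshold=10**3.2, control_threshold=10**3.2)
        rep = sample.events["reporter_intensity"]
        bright = int((rep > 10**3.2).sum())
        assert bright > 300  # the ~1% autofluorescent events are reporter-bright
        # but bright-in-both events fail the control-channel arm of the gate:
        # only the rare negative-tail leak can remain
        assert gate.positive_count(sample) <= 0.02 * bright

    def test_pre_clearance_sample_shows_no_switched_cells(self, clean_model):
        from famred import flow

        profile = OutcomeProfile(p_unedited=0.0, p_indel_only=0.0, p_cn_loh=1.0)
        pop = simulate_population(profile, 5000, seed=0, homolog_targeting=1.0)
        sample = simulate_flow_sample(pop, clean_model, seed=1, post_clearance=False)
        gate = flow.GateSpec(reporter_threshold=10**3.2, control_threshold=10**3.2)
        assert gate.positive_count(sample) == 0


class TestCnvBafTrack:
    def test_full_clonality_deletion_mean_is_minus_one(self):
        track = simulate_cnv_baf_track(
            f_del=1.0, del_interval=(100.0, 135.0), probes=500, noise_sd=0.0, seed=0
        )
        probes = track.probes
        in_del = probes["position"] >= 100.0
        assert probes.loc[in_del, "log2ratio"].mean() == pytest.approx(-1.0, abs=1e-12)
        assert probes.loc[~in_del, "log2ratio"].mean() == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "f,direction,expected",
        [
            (0.36, "del", math.log2(1.64 / 2)),   # ~ -0.286
            (0.462, "dup", math.log2(2.462 / 2)),  # ~ +0.300
        ],
    )
    def test_mosaic_segment_means_match_closed_form(self, f, direction, expected):
        kwargs = (
            {"f_del": f, "del_interval": (100.0, 135.0)}
            if direction == "del"
            else {"f_dup": f, "dup_interval": (10.0, 100.0)}
        )
        track = simulate_cnv_baf_track(probes=400, noise_sd=0.0, seed=1, **kwargs)
        lo, hi = kwargs.get("del_interval") or kwargs.get("dup_interval")
        seg = track.probes[
            (track.probes["position"] >= lo) & (track.probes["position"] <= hi)
        ]
        assert seg["log2ratio"].mean() == pytest.approx(expected, abs=1e-12)

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ConfigurationError, match="overlap"):
            simulate_cnv_baf_track(
                f_del=0.3, f_dup=0.3,
                del_interval=(100.0, 135.0), dup_interval=(90.0, 110.0),
            )

    def test_baf_shift_tracks_loh_fraction(self):
        track = simulate_cnv_baf_track(
            f_del=0.0, f_loh=0.8, loh_interval=(100.0, 135.0),
            probes=2000, noise_sd=0.0, baf_sd=0.0, seed=4,
        )
        probes = track.probes
        het = probes["baf"].notna()
        inside = het & (probes["position"] >= 100.0)
        outside = het & (probes["position"] < 100.0)
        assert np.allclose((probes.loc[inside, "baf"] - 0.5).abs(), 0.4)
        assert np.allclose(probes.loc[outside, "baf"], 0.5)


class TestQpcrPanel:
    def test_retained_snps_have_close_ct_pairs(self):
        curves = simulate_qpcr_panel([[False] * 3] * 20, seed=0)
        delta = (curves["ct_a"] - curves["ct_b"]).abs()
        assert delta.notna().all()
        assert (delta < 6).all()

    def test_lost_snps_have_single_or_distant_curves(self):
        curves = simulate_qpcr_panel([[True] * 3] * 50, seed=1)
        single = curves["ct_b"].isna()
        distant = (curves["ct_b"] - curves["ct_a"]) > 6
        assert (single | distant).all()

    def test_expected_loh_clone_count(self):
        # binomial mean: 500 clones at 0.6% -> 3 expected
        rng = np.random.default_rng(0)
        truths = rng.random(500) < 0.006
        assert 500 * 0.006 == pytest.approx(3.0)
        curves = simulate_qpcr_panel([[bool(t)] * 3 for t in truths], seed=2)
        assert curves["lost"].sum() == truths.sum() * 3


class TestSortByTracking:
    def test_exact_fraction_sizes(self, wt_profile):
        pop = simulate_population(wt_profile, 1000, seed=0)
        high, low = sort_by_tracking(pop, decile=0.1)
        assert len(high) == 100 and len(low) == 100

    def test_high_fraction_has_fewest_divisions(self, wt_profile):
        pop = simulate_population(wt_profile, 2000, seed=1, intensity_cv=0.0)
        high, low = sort_by_tracking(pop, decile=0.1)
        assert high.cells["divisions"].max() <= low.cells["divisions"].min()

    def test_too_small_population_rejected(self, wt_profile):
        pop = simulate_population(wt_profile, 5, seed=0)
        with pytest.raises(ConfigurationError):
            sort_by_tracking(pop, decile=0.1)

    def test_uniform_divisions_equalize_loh_rates(self):
        # no division effect: both fractions carry the same expected LOH rate
        profile = OutcomeProfile.from_loh_total(0.2)
        rates_h, rates_l = [], []
        for seed in range(20):
            pop = simulate_population(
                profile, 5000, seed=seed, mean_divisions=2.0, intensity_cv=0.0
            )
            high, low = sort_by_tracking(pop, decile=0.25)
            rates_h.append(high.detectable_loh_fraction())
            rates_l.append(low.detectable_loh_fraction())
        n = 20 * 1250
        se = math.sqrt(0.1 * 0.9 * 2 / n)
        assert abs(np.mean(rates_h) - np.mean(rates_l)) <= 3 * se

    def test_division_modifier_enriches_loh_in_fast_dividers(self):
        # Monte-Carlo oracle over 50 seeds: with LOH probability growing per
        # division, the most-divided (tracking-low) fraction must be richer
        profile = OutcomeProfile(
            p_unedited=0.45, p_indel_only=0.45, p_cn_loh=0.1,
            division_modifier=1.8,
        )
        diffs = []
        for seed in range(50):
            pop = simulate_population(
                profile, 4000, seed=seed, mean_divisions=2.5, intensity_cv=0.0
            )
            high, low = sort_by_tracking(pop, decile=0.1)
            diffs.append(low.detectable_loh_fraction() - high.detectable_loh_fraction())
        assert np.mean(diffs) > 0
        assert np.mean(diffs) > 2 * np.std(diffs) / math.sqrt(len(diffs))
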