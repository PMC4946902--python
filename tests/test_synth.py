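"""Synthetic study generator: behavior limits, Poisson spiking, planted gain."""

import math

import numpy as np
import pandas as pd
import pytest

from reachunc.behavior import fit_session_behavior
from reachunc.circular import circular_distance_deg, wrap_deg
from reachunc.session_io import validate_spikes, validate_trials
from reachunc.synth import (
    NeuronConfig,
    ObserverConfig,
    OD_SHAPE_MEAN,
    generate_behavior,
    generate_neurons,
    generate_session,
    generate_spikes,
    generate_study,
)


class TestObserverConfig:
    def test_implied_slope_and_dispersion_ordering(self):
        obs = ObserverConfig()
        assert obs.implied_slope("low") > obs.implied_slope("high")
        assert obs.expected_dispersion("high") > obs.expected_dispersion("low")

    def test_dispersion_monotone_in_subjective_cue_reliability(self):
        disps = [
            ObserverConfig(subj_like_kappa_high=k).expected_dispersion("high")
            for k in (0.2, 0.5, 1.0, 2.0, 5.0)
        ]
        assert all(a > b for a, b in zip(disps, disps[1:]))

    def test_validation(self):
        with pytest.raises(ValueError):
            ObserverConfig(subj_prior_kappa=-1)
        with pytest.raises(ValueError):
            ObserverConfig(n_lines=7)
        with pytest.raises(ValueError):
            NeuronConfig(od_gain=-2.0)


class TestGenerateBehavior:
    def test_layout_and_invariants(self):
        trials = generate_behavior(ObserverConfig(), 80, 60, seed=0)
        validate_trials(trials)
        assert (trials["block"] == "center_out").sum() == 80
        unc = trials[trials["block"] == "uncertainty"]
        assert (unc["condition"] == "low").sum() == 60
        assert (unc["condition"] == "high").sum() == 60
        # center-out block covers the eight standard targets
        assert set(np.round(trials[trials.block == "center_out"].target_deg)) == {
            0, 45, 90, 135, 180, -45, -90, -135
        }

    def test_deterministic_under_seed(self):
        a = generate_behavior(ObserverConfig(), 40, 40, seed=7)
        b = generate_behavior(ObserverConfig(), 40, 40, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_noiseless_cue_reliance_limit(self):
        # infinitely reliable subjective cue, no motor/decision noise
        obs = ObserverConfig(
            subj_like_kappa_low=1e12,
            subj_like_kappa_high=1e12,
            motor_kappa=math.inf,
            posterior_sampling=False,
        )
        trials = generate_behavior(obs, 8, 30, seed=1)
        unc = trials[trials["block"] == "uncertainty"]
        np.testing.assert_allclose(
            unc["reach_deg"], unc["cue_centroid_deg"], atol=1e-6
        )

    def test_equal_weights_bisect(self):
        obs = ObserverConfig(
            subj_prior_kappa=5.0,
            subj_like_kappa_low=1.0,  # x5 lines = 5 = prior kappa
            subj_like_kappa_high=1.0,
            motor_kappa=math.inf,
            posterior_sampling=False,
        )
        trials = generate_behavior(obs, 8, 30, seed=2)
        unc = trials[trials["block"] == "uncertainty"]
        midpoint = wrap_deg(
            unc["prior_mean_deg"]
            + wrap_deg(unc["cue_centroid_deg"] - unc["prior_mean_deg"]) / 2
        )
        np.testing.assert_allclose(
            circular_distance_deg(unc["reach_deg"], midpoint), 0, atol=1e-6
        )

    def test_fit_recovers_implied_slope(self):
        obs = ObserverConfig()
        trials = generate_behavior(obs, 80, 400, seed=3)
        fits, _ = fit_session_behavior(trials)
        assert fits["low"].slope == pytest.approx(obs.implied_slope("low"), abs=0.05)
        assert fits["high"].slope == pytest.approx(obs.implied_slope("high"), abs=0.05)


class TestGenerateNeurons:
    def test_m1_gets_no_gain(self):
        neurons = generate_neurons(NeuronConfig(n_pmd=10, n_m1=10, od_gain=4.0), seed=0)
        assert (neurons.loc[neurons.area == "M1", "od_gain"] == 0).all()
        assert (neurons.loc[neurons.area == "PMd", "od_gain"] == 4.0).all()

    def test_uniform_pds_fill_decoder_bins(self):
        from reachunc.decoding import build_pd_bins

        neurons = generate_neurons(NeuronConfig(n_pmd=64, n_m1=0), seed=1)
        assert len(set(build_pd_bins(neurons.pd_deg))) >= 15

    def test_seeded_determinism(self):
        a = generate_neurons(NeuronConfig(), seed=5)
        b = generate_neurons(NeuronConfig(), seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestGenerateSpikes:
    def _flat_trials(self, n, cond="low"):
        return pd.DataFrame(
            {
                "session_id": "t",
                "trial_id": np.arange(n),
                "block": "uncertainty",
                "condition": cond,
                "reach_deg": np.zeros(n),
                "t_go_s": np.full(n, 0.7),
                "t_move_on_s": np.full(n, 0.95),
                "t_target_on_s": np.zeros(n),
            }
        )

    def _flat_neuron(self, baseline=20.0, pd_deg=0.0, od_gain=0.0):
        return pd.DataFrame(
            {
                "neuron_id": ["n0"],
                "area": ["PMd"],
                "pd_deg": [pd_deg],
                "baseline_hz": [baseline],
                "beta_visual": [0.0],
                "beta_delay": [0.0],
                "beta_movement": [0.0],
                "od_gain": [od_gain],
                "gain_onset_ms": [250.0],
            }
        )

    def test_poisson_count_statistics(self):
        # untuned 20 spikes/s neuron: counts over the 1 s window after target
        # onset should be Poisson (mean 20, Fano ~ 1)
        trials = self._flat_trials(5000)
        spikes = generate_spikes(trials, self._flat_neuron(), seed=0)
        in_win = spikes[(spikes.t_s >= -0.3) & (spikes.t_s < 0.7)]
        counts = in_win.groupby("trial_id").size().reindex(trials.trial_id, fill_value=0)
        assert counts.mean() == pytest.approx(20.0, abs=0.5)
        assert counts.var() / counts.mean() == pytest.approx(1.0, abs=0.05)

    def test_support_limits(self):
        trials = self._flat_trials(100)
        spikes = generate_spikes(trials, self._flat_neuron(), seed=1)
        assert spikes.t_s.min() >= -0.3
        assert spikes.t_s.max() <= 0.95 + 0.3 + 1e-9

    def test_planted_gain_geometry(self):
        # OD neuron (pd opposite reach) gains ~od_gain in the delay period of
        # high-uncertainty trials; SD neuron (pd = reach) gains nothing
        od_gain = 5.0
        for pd_deg, expected in ((180.0, od_gain), (0.0, 0.0)):
            rates = {}
            for cond in ("low", "high"):
                trials = self._flat_trials(2000, cond=cond)
                neuron = self._flat_neuron(pd_deg=pd_deg, od_gain=od_gain)
                spikes = generate_spikes(trials, neuron, seed=2)
                delay = spikes[(spikes.t_s >= 0.3) & (spikes.t_s < 0.7)]
                rates[cond] = len(delay) / (0.4 * len(trials))
            assert rates["high"] - rates["low"] == pytest.approx(expected, abs=0.4)

    def test_referential_integrity(self):
        trials = self._flat_trials(20)
        spikes = generate_spikes(trials, self._flat_neuron(), seed=3)
        validate_spikes(spikes, trials)


class TestGenerateStudy:
    def test_ground_truth_and_determinism(self):
        s1, t1 = generate_study(
            n_sessions=4, seed=9, n_center_out=16, n_per_condition=20,
            neuron_cfg=NeuronConfig(n_pmd=4, n_m1=0),
        )
        s2, t2 = generate_study(
            n_sessions=4, seed=9, n_center_out=16, n_per_condition=20,
            neuron_cfg=NeuronConfig(n_pmd=4, n_m1=0),
        )
        pd.testing.assert_frame_equal(t1.table, t2.table)
        for a, b in zip(s1, s2):
            pd.testing.assert_frame_equal(a.trials, b.trials)
            pd.testing.assert_frame_equal(a.spikes, b.spikes)

    def test_delta_uncertainty_spans_target_range(self):
        _, truth = generate_study(
            n_sessions=12, seed=10, n_center_out=16, n_per_condition=20,
            neuron_cfg=NeuronConfig(n_pmd=2, n_m1=0),
        )
        d = truth.table.expected_delta_uncertainty
        assert d.min() >= 1.0 and d.max() <= 30.5
        assert d.max() - d.min() > 10.0

    def test_gain_law(self):
        _, truth = generate_study(
            n_sessions=10, gain_slope=0.15, gain_noise_sd=0.0, seed=11,
            n_center_out=16, n_per_condition=20,
            neuron_cfg=NeuronConfig(n_pmd=2, n_m1=0),
        )
        t = truth.table
        np.testing.assert_allclose(
            t.od_mean_gain, 0.15 * t.expected_delta_uncertainty, atol=1e-9
        )
        np.testing.assert_allclose(t.od_gain * OD_SHAPE_MEAN, t.od_mean_gain)

    def test_null_study_has_zero_gain_and_warns(self):
        with pytest.warns(UserWarning, match="degenerate gain law"):
            _, truth = generate_study(
                n_sessions=4, gain_slope=0.0, gain_noise_sd=0.0, seed=12,
                n_center_out=16, n_per_condition=20,
                neuron_cfg=NeuronConfig(n_pmd=2, n_m1=0),
            )
        assert (truth.table.od_gain == 0).all()

    def test_minimum_sessions(self):
        with pytest.raises(ValueError):
            generate_study(n_sessions=3)
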