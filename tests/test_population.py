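"""PD-offset population analyses: partition, maps, rate deltas, regressions,
subsampling and covariate controls."""

import math

import numpy as np
import pandas as pd
import pytest

from reachunc.behavior import SessionBehaviorSummary
from reachunc.pipeline import HEADLINE_WINDOW, analyze_session, run_study_regression
from reachunc.population import (
    GroupRateDelta,
    baseline_rate,
    covariate_reversal_resample,
    grouped_prior_analysis,
    group_rate_difference,
    metric_subsample_analysis,
    partition_direction_groups,
    spatiotemporal_map,
    uncertainty_activity_regression,
)
from reachunc.session_io import BASELINE, Session
from reachunc.synth import NeuronConfig, ObserverConfig, generate_session


@pytest.fixture(scope="module")
def planted_session():
    """Session with a +5 spikes/s opposite-direction gain under high uncertainty."""
    return generate_session(
        ObserverConfig(),
        NeuronConfig(n_pmd=40, n_m1=0, od_gain=5.0),
        n_center_out=80,
        n_per_condition=120,
        seed=2024,
        session_id="planted",
    )


class TestPartition:
    @pytest.mark.parametrize(
        "offset, label",
        [(0, "SD"), (180, "OD"), (90, "ORTH"), (-90, "ORTH"), (45, "ORTH"),
         (-45, "SD"), (135, "OD"), (-135, "ORTH"), (44.9, "SD"), (-180, "OD")],
    )
    def test_boundaries(self, offset, label):
        assert partition_direction_groups(offset, 0.0) == label

    def test_exhaustive_tiling(self):
        # over all integer offsets the three labels tile 90/180/90
        labels = partition_direction_groups(np.arange(-179, 181, 1.0), 0.0)
        counts = pd.Series(labels).value_counts()
        assert counts["SD"] == 90
        assert counts["ORTH"] == 180
        assert counts["OD"] == 90

    def test_depends_only_on_offset(self):
        rng = np.random.default_rng(0)
        pds = rng.uniform(-180, 180, 100)
        reach = rng.uniform(-180, 180, 100)
        a = partition_direction_groups(pds, reach)
        b = partition_direction_groups(pds + 30, reach + 30)
        np.testing.assert_array_equal(a, b)


class TestBaselineRate:
    def test_counting(self):
        trials = pd.DataFrame(
            {
                "trial_id": [0],
                "reach_deg": [0.0],
                "t_target_on_s": [0.0],
                "t_go_s": [0.8],
                "t_move_on_s": [1.0],
            }
        )
        spikes = pd.DataFrame(
            {"trial_id": [0] * 4, "neuron_id": ["n0"] * 4,
             "t_s": [-0.25, -0.15, -0.05, 0.01]}
        )
        rates = baseline_rate(spikes, trials, ["n0"])
        assert rates.loc[0, "n0"] == pytest.approx(3 / 0.3)

    def test_homogeneous_poisson_calibration(self):
        rng = np.random.default_rng(1)
        n_trials = 500
        trials = pd.DataFrame(
            {
                "trial_id": np.arange(n_trials),
                "reach_deg": np.zeros(n_trials),
                "t_target_on_s": np.zeros(n_trials),
                "t_go_s": np.full(n_trials, 0.8),
                "t_move_on_s": np.full(n_trials, 1.0),
            }
        )
        counts = rng.poisson(20 * 0.3, size=n_trials)
        rows = {
            "trial_id": np.repeat(trials.trial_id, counts),
            "neuron_id": "n0",
            "t_s": rng.uniform(-0.3, 0.0, counts.sum()),
        }
        rates = baseline_rate(pd.DataFrame(rows), trials, ["n0"])
        assert rates["n0"].mean() == pytest.approx(20.0, abs=0.5)


class TestSpatiotemporalMap:
    def test_planted_peak_at_zero_offset_during_movement(self, planted_session):
        s = planted_session
        center_out = s.block("center_out")
        pds = dict(zip(s.neurons.neuron_id, s.neurons.pd_deg))
        m = spatiotemporal_map(
            s, pds, alignment="move_on", t_start_ms=0, t_end_ms=200,
            time_bin_ms=50, trials=center_out,
        )
        mean_profile = np.nanmean(m.values, axis=1)
        # offset bins nearest zero carry the strongest movement activity
        zero_bin = np.argmin(np.abs(
            (m.offset_bin_edges[:-1] + m.offset_bin_edges[1:]) / 2
        ))
        assert np.nanargmax(mean_profile) in {zero_bin, zero_bin - 1, zero_bin + 1}

    def test_offset_invariance_under_rotation(self, planted_session):
        s = planted_session
        pds = dict(zip(s.neurons.neuron_id, s.neurons.pd_deg))
        trials = s.block("center_out")
        m1 = spatiotemporal_map(s, pds, trials=trials, t_end_ms=400)
        rot_trials = trials.copy()
        from reachunc.circular import wrap_deg

        rot_trials["reach_deg"] = wrap_deg(rot_trials["reach_deg"] + 90)
        rot_pds = {k: wrap_deg(v + 90) for k, v in pds.items()}
        m2 = spatiotemporal_map(s, rot_pds, trials=rot_trials, t_end_ms=400)
        np.testing.assert_allclose(m1.values, m2.values, equal_nan=True)

    def test_requires_tuned_neurons(self, planted_session):
        with pytest.raises(ValueError):
            spatiotemporal_map(planted_session, {})


class TestGroupRateDifference:
    def test_planted_od_gain_recovered(self, planted_session):
        s = planted_session
        pds = dict(zip(s.neurons.neuron_id, s.neurons.pd_deg))
        od = group_rate_difference(s, pds, "OD", HEADLINE_WINDOW, seed=1)
        sd = group_rate_difference(s, pds, "SD", HEADLINE_WINDOW, seed=1)
        # OD-wedge average of the (1 - cos)/2 gain shape is 0.95 x amplitude
        assert od.ci[0] <= 5.0 * 0.9502 <= od.ci[1] or abs(od.delta - 4.75) < 1.0
        assert sd.ci[0] <= 0.25 <= sd.ci[1] + 1.0

    def test_relabeling_antisymmetry(self, planted_session):
        s = planted_session
        pds = dict(zip(s.neurons.neuron_id, s.neurons.pd_deg))
        d1 = group_rate_difference(s, pds, "OD", HEADLINE_WINDOW, n_boot=100, seed=0)
        swapped = s.trials.copy()
        swapped["condition"] = swapped["condition"].map(
            {"low": "high", "high": "low", "zero": "zero"}
        )
        s2 = Session(s.session_id, swapped, s.spikes, s.neurons)
        d2 = group_rate_difference(s2, pds, "OD", HEADLINE_WINDOW, n_boot=100, seed=0)
        assert d2.delta == pytest.approx(-d1.delta, abs=1e-9)

    def test_shuffled_conditions_center_on_zero(self, planted_session):
        rng = np.random.default_rng(3)
        s = planted_session
        pds = dict(zip(s.neurons.neuron_id, s.neurons.pd_deg))
        deltas = []
        for _ in range(10):
            shuffled = s.trials.copy()
            unc = shuffled["block"] == "uncertainty"
            shuffled.loc[unc, "condition"] = rng.permutation(
                shuffled.loc[unc, "condition"].to_numpy()
            )
            s2 = Session(s.session_id, shuffled, s.spikes, s.neurons)
            deltas.append(
                group_rate_difference(s2, pds, "OD", HEADLINE_WINDOW, n_boot=100, seed=0).delta
            )
        assert abs(np.mean(deltas)) < 1.0

    def test_ci_contains_delta(self, planted_session):
        s = planted_session
        pds = dict(zip(s.neurons.neuron_id, s.neurons.pd_deg))
        for group in ("SD", "ORTH", "OD"):
            d = group_rate_difference(s, pds, group, HEADLINE_WINDOW, n_boot=100, seed=5)
            assert d.ci[0] <= d.delta <= d.ci[1]


def _fake_delta(sid, value, group="OD"):
    return GroupRateDelta(
        session_id=sid, group=group, window=HEADLINE_WINDOW,
        delta=value, ci=(value - 1, value + 1), n_neurons=10,
    )


def _fake_behavior(pairs):
    return {
        sid: SessionBehaviorSummary(sid, -0.1, unc) for sid, unc in pairs
    }


class TestRegression:
    def test_planted_linear_relation(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 30, 25)
        y = 0.2 * x + rng.normal(0, 0.5, 25)
        deltas = [_fake_delta(f"s{i}", y[i]) for i in range(25)]
        behavior = _fake_behavior([(f"s{i}", x[i]) for i in range(25)])
        res = uncertainty_activity_regression(deltas, behavior, "OD")
        assert res.slope_ci[0] <= 0.2 <= res.slope_ci[1]
        assert res.p < 0.01
        assert 0 <= res.r2 <= 1

    def test_two_sessions_underdetermined(self):
        deltas = [_fake_delta("a", 1.0), _fake_delta("b", 2.0)]
        behavior = _fake_behavior([("a", 5.0), ("b", 10.0)])
        res = uncertainty_activity_regression(deltas, behavior, "OD")
        assert res.r2 == pytest.approx(1.0)
        assert res.underdetermined

    def test_degenerate_x_rejected(self):
        deltas = [_fake_delta(f"s{i}", float(i)) for i in range(5)]
        behavior = _fake_behavior([(f"s{i}", 4.0) for i in range(5)])
        with pytest.raises(ValueError, match="degenerate"):
            uncertainty_activity_regression(deltas, behavior, "OD")


class TestSubsampleAnalysis:
    def _table(self, rng, n=20, coupled=True):
        unc = rng.uniform(0, 30, n)
        wgt = -0.3 * unc / 30 + rng.normal(0, 0.1, n)
        od = 0.15 * unc + rng.normal(0, 0.5, n) if coupled else rng.normal(0, 1, n)
        return pd.DataFrame(
            {
                "session_id": [f"s{i}" for i in range(n)],
                "od_delta": od,
                "delta_behavioral_uncertainty": unc,
                "delta_cue_weighting": wgt,
            }
        )

    def test_full_set_single_subsample(self):
        rng = np.random.default_rng(11)
        t = self._table(rng)
        res, _ = metric_subsample_analysis(
            t, subset_size=len(t), n_subsamples=5, seed=0, n_greedy_starts=0
        )
        assert len(res) == 1
        full_corr = np.corrcoef(t.od_delta, t.delta_behavioral_uncertainty)[0, 1]
        assert res.loc[0, "corr_od_unc"] == pytest.approx(full_corr)

    def test_mechanism_correlation_dominates(self):
        rng = np.random.default_rng(12)
        t = self._table(rng)
        res, _ = metric_subsample_analysis(
            t, subset_size=12, n_subsamples=300, seed=1, n_greedy_starts=0
        )
        frac = np.mean(res["corr_od_unc"] > np.abs(res["corr_od_weight"]))
        assert frac >= 0.8

    def test_determinism_and_uniqueness(self):
        rng = np.random.default_rng(13)
        t = self._table(rng)
        r1, e1 = metric_subsample_analysis(t, 12, n_subsamples=50, seed=9, n_greedy_starts=5)
        r2, e2 = metric_subsample_analysis(t, 12, n_subsamples=50, seed=9, n_greedy_starts=5)
        assert list(r1["subset"]) == list(r2["subset"])
        assert len(set(r1["subset"])) == 50
        assert e1 == e2

    def test_extreme_subsets_bracket_random_ones(self):
        rng = np.random.default_rng(14)
        t = self._table(rng)
        res, ext = metric_subsample_analysis(t, 12, n_subsamples=200, seed=2, n_greedy_starts=20)
        unc = t.delta_behavioral_uncertainty.to_numpy()
        wgt = t.delta_cue_weighting.to_numpy()

        def corr(pick):
            i = np.array(pick)
            return np.corrcoef(unc[i], wgt[i])[0, 1]

        assert corr(ext["max_unc_weight_corr"]) >= res["corr_unc_weight"].max() - 1e-9
        assert corr(ext["min_unc_weight_corr"]) <= res["corr_unc_weight"].min() + 1e-9

    def test_small_subset_rejected(self):
        rng = np.random.default_rng(15)
        with pytest.raises(ValueError):
            metric_subsample_analysis(self._table(rng), 3)


class TestCovariateReversal:
    def _trials(self, rng, hi_shift=0.2):
        n = 60
        return pd.DataFrame(
            {
                "trial_id": np.arange(2 * n),
                "block": "uncertainty",
                "condition": ["low"] * n + ["high"] * n,
                "peak_speed_cms": np.concatenate(
                    [rng.normal(20, 1, n), rng.normal(20 + hi_shift, 1, n)]
                ),
            }
        )

    def test_reverses_planted_difference(self):
        rng = np.random.default_rng(21)
        trials = self._trials(rng, hi_shift=0.2)
        sub = covariate_reversal_resample(trials, "peak_speed", seed=0)
        hi = sub[sub.condition == "high"]["peak_speed_cms"].mean()
        lo = sub[sub.condition == "low"]["peak_speed_cms"].mean()
        assert hi - lo < 0
        assert set(sub.trial_id) <= set(trials.trial_id)
        assert len(sub[sub.condition == "high"]) >= 0.5 * 60

    def test_already_reversed_is_noop(self):
        rng = np.random.default_rng(22)
        trials = self._trials(rng, hi_shift=-0.5)
        sub = covariate_reversal_resample(trials, "peak_speed", seed=0)
        assert len(sub) == len(trials)

    def test_infeasible_disjoint_supports(self):
        rng = np.random.default_rng(23)
        trials = self._trials(rng, hi_shift=50.0)
        with pytest.raises(ValueError, match="cannot reverse"):
            covariate_reversal_resample(trials, "peak_speed", seed=0)


class TestGroupedPriorAnalysis:
    def test_partition_and_recovery(self):
        rng = np.random.default_rng(31)
        deltas, behavior, prior_means = [], {}, {}
        for i in range(12):
            sid = f"s{i}"
            pm = 0.0 if i % 2 == 0 else 90.0
            unc = rng.uniform(0, 30)
            deltas.append(_fake_delta(sid, 0.2 * unc + rng.normal(0, 0.3)))
            behavior[sid] = SessionBehaviorSummary(sid, -0.1, unc)
            prior_means[sid] = pm
        out = grouped_prior_analysis(deltas, behavior, prior_means, min_group=4)
        assert set(out) == {0.0, 90.0}
        for res in out.values():
            assert res.slope > 0
            assert res.n_sessions == 6

    def test_single_group_matches_global(self):
        rng = np.random.default_rng(32)
        deltas, behavior, prior_means = [], {}, {}
        for i in range(8):
            sid = f"s{i}"
            unc = rng.uniform(0, 30)
            deltas.append(_fake_delta(sid, 0.1 * unc + rng.normal(0, 0.2)))
            behavior[sid] = SessionBehaviorSummary(sid, -0.1, unc)
            prior_means[sid] = 10.0
        out = grouped_prior_analysis(deltas, behavior, prior_means)
        ref = uncertainty_activity_regression(deltas, behavior, "OD")
        assert len(out) == 1
        assert next(iter(out.values())).slope == pytest.approx(ref.slope)
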