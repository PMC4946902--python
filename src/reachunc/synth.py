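"""Synthetic session generator emulating the uncertainty reaching experiment.

A session has two blocks.  In the *center-out* block the monkey reaches to
eight equispaced, unambiguous targets.  In the *uncertainty* block targets
are drawn from a von Mises prior (mean fixed within session) and cued by a
fan of lines drawn from a von Mises likelihood around the target; low- and
high-variance likelihoods interleave across trials.

Behavior follows a Bayesian observer: the reach aims at the mean of the
product of the observer's internal prior and a likelihood centered on the
cue centroid (effective concentration ``n_lines * subj_like_kappa``).  Two
noise sources disperse the reaches: *decision noise* drawn from the
observer's posterior (concentration ``k1 + k2``, so worse cues mean noisier
decisions — this is what makes the residual dispersion condition-dependent)
and fixed motor noise.  The experimenter-side fit then recovers the implied
cue weighting ``w = k2/(k1 + k2)`` and residual dispersion.

Spiking follows cosine-tuned Poisson neurons with piecewise-constant rates
per trial (baseline, visual, delay, movement segments).  In high-uncertainty
trials, premotor-like neurons additionally gain
``od_gain * (1 - cos(pd - reach))/2`` spikes/s from ``gain_onset_ms``
onward: nothing at the reach direction, maximal opposite it — the planted
mechanism the population analyses are built to detect.  Motor-cortex-like
neurons get no gain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .circular import (
    VonMisesParams,
    circ_summary,
    dispersion_from_resultant,
    vm_mean_resultant_length,
    vm_product_mean,
    vm_sample,
    wrap_deg,
)
from .session_io import Session, format_cue_lines

__all__ = [
    "ObserverConfig",
    "NeuronConfig",
    "StudyGroundTruth",
    "generate_behavior",
    "generate_neurons",
    "generate_spikes",
    "generate_session",
    "generate_study",
]


@dataclass
class ObserverConfig:
    """Generating and subjective parameters of one session's behavior.

    ``*_true`` parameters describe the experiment (what is displayed);
    ``subj_*`` parameters describe the observer's internal model, which is
    what the behavioral fit actually estimates.  Concentrations are von
    Mises kappas; ``motor_kappa`` may be ``inf`` for noiseless reaches and
    ``posterior_sampling=False`` disables decision noise.
    """

    prior_mean: float = 0.0
    prior_kappa_true: float = 2.0
    like_kappa_low: float = 10.0
    like_kappa_high: float = 2.0
    n_lines: int = 5
    subj_prior_kappa: float = 3.0
    subj_like_kappa_low: float = 10.0
    subj_like_kappa_high: float = 1.0
    motor_kappa: float = 100.0
    posterior_sampling: bool = True

    def __post_init__(self):
        for name in (
            "prior_kappa_true",
            "like_kappa_low",
            "like_kappa_high",
            "subj_prior_kappa",
            "subj_like_kappa_low",
            "subj_like_kappa_high",
            "motor_kappa",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_lines not in (5, 10):
            raise ValueError("n_lines must be 5 or 10")

    def effective_like_kappa(self, condition: str) -> float:
        """Observer's concentration on the cue *centroid*: n_lines fold in."""
        subj = {
            "low": self.subj_like_kappa_low,
            "high": self.subj_like_kappa_high,
        }[condition]
        return self.n_lines * subj

    def implied_slope(self, condition: str) -> float:
        """The cue weighting w = k2/(k1 + k2) the observer's rule implies."""
        k2 = self.effective_like_kappa(condition)
        return k2 / (self.subj_prior_kappa + k2)

    def expected_dispersion(self, condition: str) -> float:
        """Population residual dispersion (degrees) around the model reach.

        Decision noise (posterior concentration ``k1 + k2``) and motor noise
        convolve, so the residual resultant length is the product of the two
        component resultant lengths.
        """
        r = vm_mean_resultant_length(self.motor_kappa) if math.isfinite(
            self.motor_kappa
        ) else 1.0
        if self.posterior_sampling:
            k3 = self.subj_prior_kappa + self.effective_like_kappa(condition)
            r *= vm_mean_resultant_length(k3)
        return dispersion_from_resultant(r)

    def expected_delta_uncertainty(self) -> float:
        return self.expected_dispersion("high") - self.expected_dispersion("low")


@dataclass
class NeuronConfig:
    """Population layout and tuning ranges for one synthetic session."""

    n_pmd: int = 40
    n_m1: int = 20
    baseline_hz_range: tuple[float, float] = (3.0, 15.0)
    beta_visual_range: tuple[float, float] = (0.5, 1.5)
    beta_delay_range: tuple[float, float] = (0.5, 1.5)
    beta_movement_range: tuple[float, float] = (0.8, 2.0)
    od_gain: float = 0.0            # spikes/s added at 180 deg offset (PMd, high unc.)
    gain_onset_ms: float = 250.0    # gain absent during the early visual burst

    def __post_init__(self):
        if self.od_gain < 0:
            raise ValueError("od_gain must be nonnegative (gain only adds activity)")


@dataclass
class StudyGroundTruth:
    """Per-session generating values sufficient to score recovery tests."""

    table: pd.DataFrame          # one row per session
    neurons: dict[str, pd.DataFrame] = field(default_factory=dict)


# trial timeline constants (seconds): recording starts 300 ms before target
PRE_TARGET_S = 0.30
VISUAL_LATENCY_S = 0.05
VISUAL_END_S = 0.30
POST_MOVE_S = 0.30


def _noise(rng, kappa, n):
    if math.isinf(kappa):
        return np.zeros(n)
    return vm_sample(VonMisesParams(0.0, kappa), n, rng)


def generate_behavior(
    cfg: ObserverConfig,
    n_center_out: int = 80,
    n_per_condition: int = 120,
    seed=0,
    session_id: str = "synth",
) -> pd.DataFrame:
    """Simulate one session's trial table (both blocks).

    Center-hold and instructed-delay durations are drawn uniformly from
    700-1000 ms; with target onset as the per-trial time origin this places
    the go cue 0.7-1.0 s after the target.  Reaction times are ~250 ms and
    peak speed carries a small condition effect for the kinematic controls.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows = []
    trial_id = 0

    def _times_and_kinematics(condition):
        t_target = 0.0
        t_go = rng.uniform(0.7, 1.0)
        rt = float(np.clip(rng.normal(0.25, 0.03), 0.12, 0.5))
        if condition == "high":
            rt += 0.01
        speed = float(rng.normal(20.0, 2.0)) + (0.3 if condition == "high" else 0.0)
        return t_target, t_go, t_go + rt, rt, speed

    # center-out block: 8 equispaced targets, zero uncertainty
    targets8 = wrap_deg(np.arange(8) * 45.0)
    order = rng.permutation(np.repeat(np.arange(8), math.ceil(n_center_out / 8))[:n_center_out])
    motor = _noise(rng, cfg.motor_kappa, n_center_out)
    for i, k in enumerate(order):
        tgt = targets8[k]
        t0, tg, tm, rt, speed = _times_and_kinematics("zero")
        rows.append(
            dict(
                session_id=session_id,
                trial_id=trial_id,
                block="center_out",
                condition="zero",
                prior_mean_deg=cfg.prior_mean,
                cue_lines_deg="",
                cue_centroid_deg=tgt,
                target_deg=tgt,
                reach_deg=wrap_deg(tgt + motor[i]),
                t_target_on_s=t0,
                t_go_s=tg,
                t_move_on_s=tm,
                reaction_time_s=rt,
                peak_speed_cms=speed,
            )
        )
        trial_id += 1

    # uncertainty block: randomly interleaved low/high likelihood conditions
    conditions = rng.permutation(
        np.array(["low"] * n_per_condition + ["high"] * n_per_condition)
    )
    for cond in conditions:
        like_kappa = cfg.like_kappa_low if cond == "low" else cfg.like_kappa_high
        target = float(
            vm_sample(VonMisesParams(cfg.prior_mean, cfg.prior_kappa_true), 1, rng)[0]
        )
        lines = vm_sample(VonMisesParams(target, like_kappa), cfg.n_lines, rng)
        centroid = circ_summary(lines).mean
        k1 = cfg.subj_prior_kappa
        k2 = cfg.effective_like_kappa(cond)
        mu3 = vm_product_mean(
            VonMisesParams(cfg.prior_mean, k1), VonMisesParams(centroid, k2)
        )
        reach = mu3
        if cfg.posterior_sampling:
            reach += _noise(rng, k1 + k2, 1)[0]
        reach = wrap_deg(reach + _noise(rng, cfg.motor_kappa, 1)[0])
        t0, tg, tm, rt, speed = _times_and_kinematics(cond)
        rows.append(
            dict(
                session_id=session_id,
                trial_id=trial_id,
                block="uncertainty",
                condition=cond,
                prior_mean_deg=cfg.prior_mean,
                cue_lines_deg=format_cue_lines(lines),
                cue_centroid_deg=centroid,
                target_deg=target,
                reach_deg=float(reach),
                t_target_on_s=t0,
                t_go_s=tg,
                t_move_on_s=tm,
                reaction_time_s=rt,
                peak_speed_cms=speed,
            )
        )
        trial_id += 1
    return pd.DataFrame(rows)


def generate_neurons(cfg: NeuronConfig, seed=0, session_id: str = "synth") -> pd.DataFrame:
    """Ground-truth neuron table: uniform PDs, sampled baselines and betas.

    M1-like neurons get ``od_gain = 0`` — the uncertainty gain is a
    premotor-only mechanism by construction.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_total = cfg.n_pmd + cfg.n_m1
    if n_total < 1:
        raise ValueError("need at least one neuron")
    rows = []
    for j in range(n_total):
        area = "PMd" if j < cfg.n_pmd else "M1"
        rows.append(
            dict(
                neuron_id=f"{area.lower()}_{j:03d}",
                area=area,
                pd_deg=wrap_deg(rng.uniform(-180.0, 180.0)),
                baseline_hz=rng.uniform(*cfg.baseline_hz_range),
                beta_visual=rng.uniform(*cfg.beta_visual_range),
                beta_delay=rng.uniform(*cfg.beta_delay_range),
                beta_movement=rng.uniform(*cfg.beta_movement_range),
                od_gain=cfg.od_gain if area == "PMd" else 0.0,
                gain_onset_ms=cfg.gain_onset_ms,
            )
        )
    df = pd.DataFrame(rows)
    df.insert(0, "session_id", session_id)
    return df


def _segment_rates(trials: pd.DataFrame, neurons: pd.DataFrame):
    """Yield (start, end, rate) per piecewise-constant segment.

    ``start`` / ``end`` are per-trial arrays (seconds from target onset) and
    ``rate`` is (n_trials, n_neurons) in spikes/s.
    """
    n_t = len(trials)
    reach = trials["reach_deg"].to_numpy(dtype=float)
    t_go = (trials["t_go_s"] - trials["t_target_on_s"]).to_numpy(dtype=float)
    t_move = (trials["t_move_on_s"] - trials["t_target_on_s"]).to_numpy(dtype=float)
    is_high = (trials["condition"] == "high").to_numpy()

    pd_deg = neurons["pd_deg"].to_numpy(dtype=float)
    base = neurons["baseline_hz"].to_numpy(dtype=float)
    od_gain = neurons["od_gain"].to_numpy(dtype=float)
    gain_onset = neurons["gain_onset_ms"].to_numpy(dtype=float) / 1000.0
    if np.ptp(gain_onset) > 1e-12:
        raise ValueError("heterogeneous gain_onset_ms not supported")
    onset = float(gain_onset[0]) if len(gain_onset) else 0.25

    cos_off = np.cos(np.radians(reach[:, None] - pd_deg[None, :]))
    gain_shape = (1.0 - cos_off) / 2.0  # 0 at PD = reach, 1 opposite
    gain = np.where(is_high[:, None], od_gain[None, :] * gain_shape, 0.0)

    def epoch_rate(beta_col):
        beta = neurons[beta_col].to_numpy(dtype=float)
        return base[None, :] * np.exp(beta[None, :] * cos_off)

    baseline = np.broadcast_to(base[None, :], (n_t, len(neurons)))
    visual = epoch_rate("beta_visual")
    delay = epoch_rate("beta_delay")
    movement = epoch_rate("beta_movement")

    segs = [
        (np.full(n_t, -PRE_TARGET_S), np.full(n_t, 0.0), baseline),
        (np.full(n_t, 0.0), np.full(n_t, VISUAL_LATENCY_S), baseline),
        (np.full(n_t, VISUAL_LATENCY_S), np.full(n_t, onset), visual),
        (np.full(n_t, onset), np.full(n_t, VISUAL_END_S), visual + gain),
        (np.full(n_t, VISUAL_END_S), t_go, delay + gain),
        (t_go, t_move, delay + gain),
        (t_move, t_move + POST_MOVE_S, movement + gain),
    ]
    return segs


def generate_spikes(trials: pd.DataFrame, neurons: pd.DataFrame, seed=0) -> pd.DataFrame:
    """Poisson spike trains under the piecewise-constant rate model.

    Within each constant segment the spike count is Poisson with mean
    rate x duration and times are uniform, which together realize an
    inhomogeneous Poisson process.  Times are seconds from target onset.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_t, n_n = len(trials), len(neurons)
    trial_ids = trials["trial_id"].to_numpy()
    neuron_ids = neurons["neuron_id"].to_numpy()

    all_trial, all_neuron, all_t = [], [], []
    for start, end, rate in _segment_rates(trials, neurons):
        dur = np.maximum(end - start, 0.0)
        assert np.all(rate >= -1e-12), "negative rate in generator"
        lam = rate * dur[:, None]
        counts = rng.poisson(lam)
        total = int(counts.sum())
        if total == 0:
            continue
        flat = counts.ravel()
        ti, ni = np.divmod(np.arange(n_t * n_n), n_n)
        rep_trial = np.repeat(ti, flat)
        rep_neuron = np.repeat(ni, flat)
        u = rng.random(total)
        times = np.repeat(start[ti], flat) + u * np.repeat(dur[ti], flat)
        all_trial.append(trial_ids[rep_trial])
        all_neuron.append(neuron_ids[rep_neuron])
        all_t.append(times)
    if not all_trial:
        return pd.DataFrame(columns=["trial_id", "neuron_id", "t_s"])
    spikes = pd.DataFrame(
        {
            "trial_id": np.concatenate(all_trial),
            "neuron_id": np.concatenate(all_neuron),
            "t_s": np.concatenate(all_t),
        }
    )
    return spikes.sort_values(["trial_id", "neuron_id", "t_s"], kind="stable").reset_index(
        drop=True
    )


def generate_session(
    observer: ObserverConfig,
    neuron_cfg: NeuronConfig,
    n_center_out: int = 80,
    n_per_condition: int = 120,
    seed=0,
    session_id: str = "synth",
) -> Session:
    """One complete synthetic session with ground truth attached."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    trials = generate_behavior(
        observer, n_center_out, n_per_condition, rng, session_id=session_id
    )
    neurons = generate_neurons(neuron_cfg, rng, session_id=session_id)
    spikes = generate_spikes(trials, neurons, rng)
    meta = {
        "observer": asdict(observer),
        "neuron_cfg": asdict(neuron_cfg),
        "w_low_true": observer.implied_slope("low"),
        "w_high_true": observer.implied_slope("high"),
        "expected_delta_uncertainty": observer.expected_delta_uncertainty(),
        "od_gain": neuron_cfg.od_gain,
    }
    return Session(
        session_id=session_id, trials=trials, spikes=spikes, neurons=neurons, meta=meta
    )


# mean of the gain shape (1 - cos)/2 over the OD wedge (offsets within 45
# degrees of 180): 1/2 + sqrt(2)/pi
OD_SHAPE_MEAN = 0.5 + math.sqrt(2.0) / math.pi


def _solve_subj_like_high(
    target_delta_deg: float, base: ObserverConfig
) -> float | None:
    """Subjective high-condition line kappa giving a target expected
    delta of behavioral uncertainty; None when infeasible."""
    from scipy.optimize import brentq

    def f(subj_like_high):
        obs = ObserverConfig(
            **{**asdict(base), "subj_like_kappa_high": subj_like_high}
        )
        return obs.expected_delta_uncertainty() - target_delta_deg

    lo, hi = 1e-3, base.subj_like_kappa_low
    if f(lo) < 0 or f(hi) > 0:
        return None
    return float(brentq(f, lo, hi, xtol=1e-6))


def generate_study(
    n_sessions: int = 20,
    gain_slope: float = 0.15,
    gain_noise_sd: float = 0.8,
    seed=0,
    neuron_cfg: NeuronConfig | None = None,
    n_center_out: int = 80,
    n_per_condition: int = 150,
    n_lines: int = 5,
    prior_means: tuple[float, ...] = (0.0, 90.0),
    delta_uncertainty_range: tuple[float, float] = (2.0, 30.0),
    subj_prior_kappa_range: tuple[float, float] = (1.5, 5.0),
    subj_like_kappa_low_range: tuple[float, float] = (1.5, 10.0),
    motor_kappa_range: tuple[float, float] = (60.0, 150.0),
) -> tuple[list[Session], StudyGroundTruth]:
    """A study of sessions spanning a range of behavioral uncertainty deltas.

    Each session draws a target expected delta of behavioral uncertainty
    uniformly from ``delta_uncertainty_range`` (capped at what the session's
    prior and motor noise make feasible) and solves for the subjective
    high-uncertainty likelihood concentration that produces it; prior
    concentration and motor noise also vary per session, which partially
    decorrelates the cue-weighting delta from the uncertainty delta.  The
    planted premotor gain follows the linear law

        mean OD-wedge gain = max(0, gain_slope * delta_uncertainty + noise)

    so the cross-session regression of OD activity differences on behavioral
    uncertainty differences has generating slope ``gain_slope`` (spikes/s
    per degree); the corresponding 180-degree-offset amplitude is stored as
    ``od_gain``.  ``gain_slope = 0`` gives the null study.
    """
    if n_sessions < 4:
        raise ValueError("need at least 4 sessions")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    neuron_cfg = neuron_cfg or NeuronConfig()
    sessions, rows = [], []
    d_lo, d_hi = delta_uncertainty_range
    for i in range(n_sessions):
        lo_lk, hi_lk = subj_like_kappa_low_range
        base = ObserverConfig(
            prior_mean=prior_means[i % len(prior_means)],
            n_lines=n_lines,
            subj_prior_kappa=float(rng.uniform(*subj_prior_kappa_range)),
            # per-session variation in low-condition cue reliability keeps the
            # cue-weighting delta only weakly coupled to the uncertainty delta
            subj_like_kappa_low=float(
                np.exp(rng.uniform(math.log(lo_lk), math.log(hi_lk)))
            ),
            motor_kappa=float(rng.uniform(*motor_kappa_range)),
        )
        # feasible ceiling: delta at vanishing subjective cue reliability
        limit = ObserverConfig(
            **{**asdict(base), "subj_like_kappa_high": 1e-3}
        ).expected_delta_uncertainty()
        target = float(rng.uniform(d_lo, min(d_hi, 0.95 * limit)))
        subj_high = _solve_subj_like_high(target, base)
        if subj_high is None:  # pragma: no cover - ranges keep this feasible
            subj_high = 1e-3
        obs = ObserverConfig(
            **{**asdict(base), "subj_like_kappa_high": subj_high}
        )
        delta_unc = obs.expected_delta_uncertainty()
        od_mean_gain = max(0.0, gain_slope * delta_unc + rng.normal(0.0, gain_noise_sd))
        od_gain = od_mean_gain / OD_SHAPE_MEAN
        cfg_i = NeuronConfig(
            n_pmd=neuron_cfg.n_pmd,
            n_m1=neuron_cfg.n_m1,
            baseline_hz_range=neuron_cfg.baseline_hz_range,
            beta_visual_range=neuron_cfg.beta_visual_range,
            beta_delay_range=neuron_cfg.beta_delay_range,
            beta_movement_range=neuron_cfg.beta_movement_range,
            od_gain=od_gain,
            gain_onset_ms=neuron_cfg.gain_onset_ms,
        )
        sid = f"s{i:03d}"
        sess = generate_session(
            obs, cfg_i, n_center_out, n_per_condition, rng, session_id=sid
        )
        sessions.append(sess)
        rows.append(
            dict(
                session_id=sid,
                prior_mean=obs.prior_mean,
                subj_like_kappa_high=obs.subj_like_kappa_high,
                subj_prior_kappa=obs.subj_prior_kappa,
                motor_kappa=obs.motor_kappa,
                w_low_true=obs.implied_slope("low"),
                w_high_true=obs.implied_slope("high"),
                expected_delta_uncertainty=delta_unc,
                od_gain=od_gain,
                od_mean_gain=od_mean_gain,
            )
        )
    truth = StudyGroundTruth(
        table=pd.DataFrame(rows),
        neurons={s.session_id: s.neurons for s in sessions},
    )
    if len(truth.table["od_gain"].unique()) == 1 and n_sessions > 1:
        import warnings

        warnings.warn("degenerate gain law: all sessions share the same od_gain")
    return sessions, truth
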