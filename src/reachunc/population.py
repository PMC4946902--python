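"""Population analyses of uncertainty-dependent activity.

Neurons are partitioned per trial by the offset between their preferred
direction (PD) and the reach direction: same-direction (SD, |offset| < 45),
opposite-direction (OD, within 45 of the anti-reach direction) and orthogonal
(ORTH, the rest).  The analyses ask whether the high-minus-low uncertainty
difference in baseline-subtracted firing rate — especially for OD neurons —
scales across sessions with the behavioral uncertainty difference measured
from the cue-integration fits.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .circular import wrap_deg
from .session_io import BASELINE, EpochWindow, Session

__all__ = [
    "PopulationMap",
    "GroupRateDelta",
    "RegressionResult",
    "partition_direction_groups",
    "baseline_rate",
    "windowed_rates",
    "spatiotemporal_map",
    "group_rate_difference",
    "uncertainty_activity_regression",
    "sliding_window_regression",
    "metric_subsample_analysis",
    "covariate_reversal_resample",
    "grouped_prior_analysis",
]

GROUPS = ("SD", "ORTH", "OD")


def partition_direction_groups(pd_deg, reach_deg):
    """Label neurons by PD-minus-reach offset: SD, ORTH or OD.

    Offsets in [-45, 45) are SD, offsets in [135, 180] or [-180, -135) are
    OD, everything else ORTH.  Half-open boundaries make the three labels
    tile the circle exactly.  Vectorized over inputs.
    """
    offset = wrap_deg(np.asarray(pd_deg, dtype=float) - np.asarray(reach_deg, dtype=float))
    scalar = np.ndim(offset) == 0
    offset = np.atleast_1d(offset)
    labels = np.full(offset.shape, "ORTH", dtype=object)
    labels[(offset >= -45.0) & (offset < 45.0)] = "SD"
    labels[(offset >= 135.0) | (offset < -135.0)] = "OD"
    return labels[0] if scalar else labels


def _rate_matrix(
    spikes: pd.DataFrame, trials: pd.DataFrame, window: EpochWindow, neuron_ids
) -> pd.DataFrame:
    """Firing rate (spikes/s) per trial x neuron within a window."""
    t = spikes["t_s"].to_numpy(dtype=float)
    if window.alignment == "move_on":
        move = trials["t_move_on_s"].to_numpy() - trials["t_target_on_s"].to_numpy()
        lat = pd.Series(move, index=trials["trial_id"].to_numpy())
        t = t - lat.reindex(spikes["trial_id"].to_numpy()).to_numpy()
    lo, hi = window.start_ms / 1000.0, window.end_ms / 1000.0
    inside = (t >= lo) & (t < hi)
    sub = spikes.loc[inside]

    trial_ids = trials["trial_id"].to_numpy()
    sub = sub[sub["trial_id"].isin(trial_ids)]
    tpos = pd.Series(np.arange(len(trial_ids)), index=trial_ids)
    npos = pd.Series(np.arange(len(neuron_ids)), index=list(neuron_ids))
    counts = np.zeros((len(trial_ids), len(neuron_ids)))
    if len(sub):
        known = sub["neuron_id"].isin(npos.index)
        sub = sub.loc[known]
        ti = tpos.reindex(sub["trial_id"].to_numpy()).to_numpy().astype(int)
        ni = npos.reindex(sub["neuron_id"].to_numpy()).to_numpy().astype(int)
        np.add.at(counts, (ti, ni), 1.0)
    return pd.DataFrame(counts / window.duration_s, index=trial_ids, columns=list(neuron_ids))


def baseline_rate(
    spikes: pd.DataFrame, trials: pd.DataFrame, neuron_ids, window: EpochWindow = BASELINE
) -> pd.DataFrame:
    """Pre-target baseline rate (spikes/s) per trial x neuron."""
    return _rate_matrix(spikes, trials, window, neuron_ids)


def windowed_rates(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    window: EpochWindow,
    neuron_ids,
    baseline_subtract: bool = True,
) -> pd.DataFrame:
    """Window rates, optionally baseline-subtracted per trial."""
    rates = _rate_matrix(spikes, trials, window, neuron_ids)
    if baseline_subtract:
        rates = rates - baseline_rate(spikes, trials, neuron_ids)
    return rates


@dataclass
class PopulationMap:
    """Spatiotemporal activity map: mean baseline-subtracted rate indexed by
    (PD - reach) offset bin x time bin."""

    alignment: str
    time_bin_edges: np.ndarray     # ms
    offset_bin_edges: np.ndarray   # degrees, tiling (-180, 180]
    values: np.ndarray             # (n_offset_bins, n_time_bins), NaN when empty
    n_contributions: np.ndarray    # same shape, ints


@dataclass
class GroupRateDelta:
    """High-minus-low uncertainty rate difference for one neuron group."""

    session_id: str
    group: str
    window: EpochWindow
    delta: float                   # spikes/s
    ci: tuple[float, float]        # bootstrap 95% bounds
    n_neurons: int


@dataclass
class RegressionResult:
    """OLS of a session-level rate delta on a behavioral delta."""

    group: str
    window: str
    slope: float        # spikes/s per degree
    intercept: float
    r2: float
    p: float
    n_sessions: int
    slope_ci: tuple[float, float] = (math.nan, math.nan)
    underdetermined: bool = False


def spatiotemporal_map(
    session: Session,
    pds: dict[str, float],
    alignment: str = "target_on",
    time_bin_ms: float = 20.0,
    n_offset_bins: int = 16,
    t_start_ms: float = -200.0,
    t_end_ms: float = 1000.0,
    trials: pd.DataFrame | None = None,
) -> PopulationMap:
    """Average baseline-subtracted rate by (PD - reach) offset and time.

    ``pds`` maps neuron_id -> preferred direction for the epoch of interest;
    only neurons present in the mapping (i.e. significantly tuned) contribute.
    """
    if not pds:
        raise ValueError("no tuned neurons supplied")
    trials = session.trials if trials is None else trials
    spikes = session.spikes[
        session.spikes["neuron_id"].isin(pds.keys())
        & session.spikes["trial_id"].isin(trials["trial_id"])
    ]

    time_edges = np.arange(t_start_ms, t_end_ms + time_bin_ms / 2, time_bin_ms)
    offset_edges = np.linspace(-180.0, 180.0, n_offset_bins + 1)
    n_time = len(time_edges) - 1

    neuron_ids = sorted(pds.keys())
    pd_arr = np.array([pds[n] for n in neuron_ids])
    base = baseline_rate(spikes, trials, neuron_ids).to_numpy()

    reach = trials["reach_deg"].to_numpy(dtype=float)
    # offset bin per (trial, neuron)
    offs = wrap_deg(pd_arr[None, :] - reach[:, None])
    # map 180 into the last bin (edges are right-open except the top)
    obin = np.clip(((offs + 180.0) / (360.0 / n_offset_bins)).astype(int), 0, n_offset_bins - 1)

    t = spikes["t_s"].to_numpy(dtype=float)
    if alignment == "move_on":
        move = trials["t_move_on_s"].to_numpy() - trials["t_target_on_s"].to_numpy()
        lat = pd.Series(move, index=trials["trial_id"].to_numpy())
        t = t - lat.reindex(spikes["trial_id"].to_numpy()).to_numpy()

    trial_ids = trials["trial_id"].to_numpy()
    tpos = pd.Series(np.arange(len(trial_ids)), index=trial_ids)
    npos = pd.Series(np.arange(len(neuron_ids)), index=neuron_ids)
    ti = tpos.reindex(spikes["trial_id"].to_numpy()).to_numpy().astype(int)
    ni = npos.reindex(spikes["neuron_id"].to_numpy()).to_numpy().astype(int)
    tb = np.floor((t * 1000.0 - t_start_ms) / time_bin_ms).astype(int)
    keep = (tb >= 0) & (tb < n_time)

    counts = np.zeros((len(trial_ids), len(neuron_ids), n_time))
    np.add.at(counts, (ti[keep], ni[keep], tb[keep]), 1.0)
    rates = counts / (time_bin_ms / 1000.0) - base[:, :, None]

    values = np.zeros((n_offset_bins, n_time))
    n_contrib = np.zeros((n_offset_bins, n_time), dtype=int)
    for b in range(n_offset_bins):
        mask = obin == b
        n_cells = int(mask.sum())
        if n_cells:
            values[b] = rates[mask].mean(axis=0)
            n_contrib[b] = n_cells
    values[n_contrib == 0] = np.nan
    return PopulationMap(
        alignment=alignment,
        time_bin_edges=time_edges,
        offset_bin_edges=offset_edges,
        values=values,
        n_contributions=n_contrib,
    )


def group_rate_difference(
    session: Session,
    pds: dict[str, float],
    group: str,
    window: EpochWindow,
    n_boot: int = 200,
    seed=0,
    baseline_subtract: bool = True,
    trials: pd.DataFrame | None = None,
) -> GroupRateDelta | None:
    """Mean high-minus-low rate difference over a PD-offset neuron group.

    Per neuron and condition, the baseline-subtracted window rate is averaged
    over the trials on which the neuron belongs to ``group`` (membership is
    per trial because the reach direction varies).  ``delta`` averages the
    per-neuron high-minus-low differences; the CI bootstraps over trials.
    Returns ``None`` when no neuron ever falls in the group (missing value,
    not zero).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    trials = session.trials if trials is None else trials
    unc = trials[trials["block"] == "uncertainty"]
    neuron_ids = sorted(pds.keys())
    if not neuron_ids:
        return None
    rates = windowed_rates(
        session.spikes, unc, window, neuron_ids, baseline_subtract=baseline_subtract
    ).to_numpy()
    reach = unc["reach_deg"].to_numpy(dtype=float)
    pd_arr = np.array([pds[n] for n in neuron_ids])
    labels = np.empty((len(unc), len(neuron_ids)), dtype=object)
    for j in range(len(neuron_ids)):
        labels[:, j] = partition_direction_groups(
            np.full(len(unc), pd_arr[j]), reach
        )
    in_group = labels == group
    cond = unc["condition"].to_numpy()
    is_high = cond == "high"
    is_low = cond == "low"
    if not (is_high.any() and is_low.any()):
        raise ValueError("both uncertainty conditions required")

    def _delta(trial_mask_high, trial_mask_low):
        with np.errstate(invalid="ignore"):
            num_h = np.where(in_group & trial_mask_high[:, None], rates, 0.0).sum(axis=0)
            den_h = (in_group & trial_mask_high[:, None]).sum(axis=0)
            num_l = np.where(in_group & trial_mask_low[:, None], rates, 0.0).sum(axis=0)
            den_l = (in_group & trial_mask_low[:, None]).sum(axis=0)
        ok = (den_h > 0) & (den_l > 0)
        if not ok.any():
            return math.nan, 0
        d = num_h[ok] / den_h[ok] - num_l[ok] / den_l[ok]
        return float(d.mean()), int(ok.sum())

    delta, n_neurons = _delta(is_high, is_low)
    if n_neurons == 0:
        return None
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    hi_idx = np.flatnonzero(is_high)
    lo_idx = np.flatnonzero(is_low)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        mh = np.zeros(len(unc), dtype=bool)
        ml = np.zeros(len(unc), dtype=bool)
        # resampling with replacement can repeat trials; weight via bincount
        rh = rng.choice(hi_idx, size=hi_idx.size, replace=True)
        rl = rng.choice(lo_idx, size=lo_idx.size, replace=True)
        wh = np.bincount(rh, minlength=len(unc)).astype(float)
        wl = np.bincount(rl, minlength=len(unc)).astype(float)
        num_h = (rates * in_group * wh[:, None]).sum(axis=0)
        den_h = (in_group * wh[:, None]).sum(axis=0)
        num_l = (rates * in_group * wl[:, None]).sum(axis=0)
        den_l = (in_group * wl[:, None]).sum(axis=0)
        ok = (den_h > 0) & (den_l > 0)
        boots[b] = (num_h[ok] / den_h[ok] - num_l[ok] / den_l[ok]).mean() if ok.any() else np.nan
    lo_ci, hi_ci = np.nanpercentile(boots, [2.5, 97.5])
    return GroupRateDelta(
        session_id=session.session_id,
        group=group,
        window=window,
        delta=delta,
        ci=(float(min(lo_ci, delta)), float(max(hi_ci, delta))),
        n_neurons=n_neurons,
    )


def uncertainty_activity_regression(
    deltas, behavior, group: str, window_name: str = ""
) -> RegressionResult:
    """OLS of per-session rate deltas on per-session behavioral uncertainty deltas.

    ``deltas`` is a list of :class:`GroupRateDelta` (one per session) and
    ``behavior`` a mapping session_id -> SessionBehaviorSummary (or an object
    with ``delta_behavioral_uncertainty``).
    """
    pairs = []
    for d in deltas:
        if d is None or d.group != group or not np.isfinite(d.delta):
            continue
        summ = behavior.get(d.session_id) if hasattr(behavior, "get") else None
        if summ is None or not np.isfinite(summ.delta_behavioral_uncertainty):
            continue
        pairs.append((summ.delta_behavioral_uncertainty, d.delta))
    if len(pairs) < 2:
        raise ValueError("need at least 2 sessions with both quantities")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: all behavioral deltas equal")
    res = stats.linregress(x, y)
    n = len(x)
    underdetermined = n < 4
    if n > 2:
        tcrit = stats.t.ppf(0.975, n - 2)
        ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    else:
        ci = (math.nan, math.nan)
    return RegressionResult(
        group=group,
        window=window_name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(res.pvalue) if n > 2 else math.nan,
        n_sessions=n,
        slope_ci=(float(ci[0]), float(ci[1])),
        underdetermined=underdetermined,
    )


def default_sliding_windows(
    delay_span_ms: tuple[float, float] = (300.0, 700.0),
    movement_span_ms: tuple[float, float] = (0.0, 300.0),
    step_ms: float = 100.0,
) -> list[EpochWindow]:
    """Visual window plus 100 ms steps across the delay and movement periods."""
    windows = [EpochWindow("visual", "target_on", 50.0, 250.0)]
    lo, hi = delay_span_ms
    t = lo
    while t + step_ms <= hi + 1e-9:
        windows.append(EpochWindow(f"delay_{int(t)}", "target_on", t, t + step_ms))
        t += step_ms
    lo, hi = movement_span_ms
    t = lo
    while t + step_ms <= hi + 1e-9:
        windows.append(EpochWindow(f"move_{int(t)}", "move_on", t, t + step_ms))
        t += step_ms
    return windows


def window_epoch_name(window: EpochWindow) -> str:
    """Which canonical epoch's PDs a sliding window should use."""
    if window.alignment == "move_on":
        return "movement"
    if window.name.startswith("visual") or window.end_ms <= 300.0:
        return "visual"
    return "delay"


def sliding_window_regression(
    sessions_deltas: dict[str, list],
    behavior: dict,
    windows: list[EpochWindow],
) -> list[RegressionResult]:
    """One regression per (group x window) from precomputed per-window deltas.

    ``sessions_deltas`` maps window name -> list of GroupRateDelta across
    sessions (all groups mixed).  Window-level failures are recorded as
    ``None`` entries rather than raised.
    """
    out = []
    for window in windows:
        per = sessions_deltas.get(window.name, [])
        for group in GROUPS:
            try:
                out.append(
                    uncertainty_activity_regression(per, behavior, group, window.name)
                )
            except ValueError:
                out.append(None)
    return out


def metric_subsample_analysis(
    table: pd.DataFrame,
    subset_size: int,
    n_subsamples: int = 1000,
    seed=0,
    n_greedy_starts: int = 200,
):
    """Correlation triples over random session subsets, plus extreme subsets.

    ``table`` needs columns ``od_delta``, ``delta_behavioral_uncertainty``
    and ``delta_cue_weighting`` (one row per session).  For each unique
    random subset the three pairwise Pearson correlations are computed:
    (OD vs behavioral uncertainty, OD vs cue weighting, uncertainty vs cue
    weighting).  A greedy swap search from random starts returns the subsets
    maximizing / minimizing the third correlation.
    """
    n = len(table)
    if subset_size < 4:
        raise ValueError("subset_size must be >= 4")
    if subset_size > n:
        raise ValueError("subset_size exceeds number of sessions")
    od = table["od_delta"].to_numpy(dtype=float)
    unc = table["delta_behavioral_uncertainty"].to_numpy(dtype=float)
    wgt = table["delta_cue_weighting"].to_numpy(dtype=float)

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    def _corr(a, b):
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return math.nan
        return float(np.corrcoef(a, b)[0, 1])

    max_unique = math.comb(n, subset_size)
    target = min(n_subsamples, max_unique)
    seen = set()
    subsets = []
    while len(subsets) < target:
        pick = tuple(sorted(rng.choice(n, size=subset_size, replace=False)))
        if pick in seen:
            continue
        seen.add(pick)
        subsets.append(pick)
    rows = []
    for pick in subsets:
        i = np.array(pick)
        rows.append(
            {
                "corr_od_unc": _corr(od[i], unc[i]),
                "corr_od_weight": _corr(od[i], wgt[i]),
                "corr_unc_weight": _corr(unc[i], wgt[i]),
                "subset": pick,
            }
        )
    results = pd.DataFrame(rows)

    def _greedy(maximize: bool):
        best_pick, best_val = None, -math.inf
        sign = 1.0 if maximize else -1.0
        for _ in range(n_greedy_starts):
            current = list(rng.choice(n, size=subset_size, replace=False))
            improved = True
            while improved:
                improved = False
                val = sign * _corr(unc[current], wgt[current])
                outside = [j for j in range(n) if j not in current]
                for pos, cand in itertools.product(range(subset_size), outside):
                    trial = current.copy()
                    trial[pos] = cand
                    v = sign * _corr(unc[trial], wgt[trial])
                    if v > val + 1e-12:
                        current, val, improved = trial, v, True
                        break
            if val > best_val:
                best_val, best_pick = val, tuple(sorted(current))
        return best_pick

    if n_greedy_starts > 0:
        extremes = {
            "max_unc_weight_corr": _greedy(True),
            "min_unc_weight_corr": _greedy(False),
        }
    else:
        extremes = {}
    return results, extremes


def covariate_reversal_resample(
    trials: pd.DataFrame, covariate: str, seed=0, min_retained: float = 0.5
) -> pd.DataFrame:
    """Subsample uncertainty trials to reverse a kinematic covariate's
    condition difference.

    If the full set has e.g. higher mean peak speed on high-uncertainty
    trials, trim the highest-covariate high trials (rank-based) until the
    sign of ``mean_high - mean_low`` flips.  Used to show the neural
    uncertainty effect is not a kinematic artifact.
    """
    col = {"peak_speed": "peak_speed_cms", "reaction_time": "reaction_time_s"}.get(
        covariate, covariate
    )
    if col not in trials.columns:
        raise ValueError(f"covariate column {col!r} missing")
    unc = trials[trials["block"] == "uncertainty"]
    hi = unc[unc["condition"] == "high"]
    lo = unc[unc["condition"] == "low"]
    if hi.empty or lo.empty:
        raise ValueError("both uncertainty conditions required")
    diff = hi[col].mean() - lo[col].mean()
    if diff == 0:
        raise ValueError("condition means already equal; nothing to reverse")
    if diff < 0:
        # already reversed relative to the expected positive effect: no-op
        return trials.copy()

    # trim the extreme tail of the high condition until the sign flips
    hi_sorted = hi.sort_values(col, ascending=True)
    n_hi = len(hi_sorted)
    min_keep = max(int(math.ceil(min_retained * n_hi)), 2)
    for keep in range(n_hi - 1, min_keep - 1, -1):
        kept = hi_sorted.iloc[:keep]
        if kept[col].mean() - lo[col].mean() < 0:
            keep_ids = set(kept["trial_id"]) | set(lo["trial_id"]) | set(
                trials.loc[trials["block"] != "uncertainty", "trial_id"]
            )
            return trials[trials["trial_id"].isin(keep_ids)].copy()
    raise ValueError(
        f"cannot reverse {covariate} difference while retaining "
        f">= {min_retained:.0%} of high-condition trials"
    )


def grouped_prior_analysis(
    deltas_by_session: list,
    behavior: dict,
    prior_means: dict[str, float],
    group: str = "OD",
    window_name: str = "",
    tol_deg: float = 45.0,
    min_group: int = 4,
) -> dict[float, RegressionResult]:
    """Rerun the uncertainty regression within groups of sessions sharing a
    prior mean direction.

    Sessions are partitioned by rounding their prior mean to the nearest
    cluster center found among the distinct values (within ``tol_deg``).
    Undersized groups are skipped.
    """
    # cluster prior means by wrapped proximity
    centers: list[float] = []
    assign: dict[str, float] = {}
    for sid, pm in prior_means.items():
        placed = False
        for c in centers:
            if abs(wrap_deg(pm - c)) <= tol_deg:
                assign[sid] = c
                placed = True
                break
        if not placed:
            centers.append(pm)
            assign[sid] = pm
    out: dict[float, RegressionResult] = {}
    for c in centers:
        sids = {s for s, cc in assign.items() if cc == c}
        sub = [d for d in deltas_by_session if d is not None and d.session_id in sids]
        if len({d.session_id for d in sub if d.group == group}) < min_group:
            continue
        try:
            out[c] = uncertainty_activity_regression(sub, behavior, group, window_name)
        except ValueError:
            continue
    return out
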