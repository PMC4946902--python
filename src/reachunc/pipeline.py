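"""End-to-end orchestration: session analyses and cross-session studies.

These helpers wire the modules together the way the analysis scripts and the
command line run them: fit behavior per session, fit center-out tuning with
bootstrap PD significance, compute SD/ORTH/OD rate deltas in analysis
windows, regress the deltas on behavioral uncertainty across sessions, and
decode reach direction per trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import BehaviorFit, SessionBehaviorSummary, fit_session_behavior
from .decoding import DecodeResult, compare_conditions, decode_session
from .population import (
    GROUPS,
    GroupRateDelta,
    RegressionResult,
    group_rate_difference,
    uncertainty_activity_regression,
    window_epoch_name,
)
from .session_io import DELAY, MOVEMENT, VISUAL, EpochWindow, Session
from .tuning import bootstrap_pd_significance, epoch_spike_counts

__all__ = [
    "HEADLINE_WINDOW",
    "SessionAnalysis",
    "fit_session_tuning",
    "significant_pds",
    "analyze_session",
    "run_study_regression",
    "run_study_decoding",
]

# the headline comparison window: late delay, 500-700 ms after target onset
HEADLINE_WINDOW = EpochWindow("delay_late", "target_on", 500.0, 700.0)

EPOCH_WINDOWS = {"visual": VISUAL, "delay": DELAY, "movement": MOVEMENT}


@dataclass
class SessionAnalysis:
    """Everything downstream analyses need from one session."""

    session_id: str
    behavior_fits: dict[str, BehaviorFit]
    behavior: SessionBehaviorSummary
    tuning: dict[str, dict]          # epoch -> neuron_id -> TuningFit
    deltas: dict[str, list]          # window name -> [GroupRateDelta per group]


def fit_session_tuning(
    session: Session,
    epochs: tuple[str, ...] = ("visual", "delay", "movement"),
    n_boot: int = 200,
    criterion_deg: float = 45.0,
    seed=0,
    area: str | None = "PMd",
) -> dict[str, dict]:
    """Bootstrap tuning fits on the center-out block, per epoch.

    PDs are always characterized from the zero-uncertainty block.  When the
    session carries a ground-truth neuron table and ``area`` is given, only
    that area's neurons are fit (the population analyses target premotor
    cortex; pass ``area=None`` to fit everything).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    center_out = session.block("center_out")
    spikes = session.spikes
    if area is not None and session.neurons is not None and "area" in session.neurons:
        keep = set(session.neurons.loc[session.neurons["area"] == area, "neuron_id"])
        spikes = spikes[spikes["neuron_id"].isin(keep)]
    out: dict[str, dict] = {}
    for epoch_name in epochs:
        epoch = EPOCH_WINDOWS[epoch_name]
        counts = epoch_spike_counts(spikes, center_out, epoch)
        fits = {}
        for nid, data in counts.items():
            try:
                fit = bootstrap_pd_significance(
                    data, n_boot=n_boot, criterion_deg=criterion_deg, seed=rng
                )
            except ValueError:
                continue
            fit.session_id = session.session_id
            fits[nid] = fit
        out[epoch_name] = fits
    return out


def significant_pds(tuning_epoch: dict) -> dict[str, float]:
    """neuron_id -> PD for neurons passing the bootstrap criterion."""
    return {
        nid: f.pd
        for nid, f in tuning_epoch.items()
        if f.significant and np.isfinite(f.pd)
    }


def analyze_session(
    session: Session,
    windows: list[EpochWindow] | None = None,
    n_boot_tuning: int = 200,
    n_boot_delta: int = 200,
    criterion_deg: float = 45.0,
    seed=0,
    area: str | None = "PMd",
) -> SessionAnalysis:
    """Behavior fit plus PD-group rate deltas for the requested windows."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    windows = [HEADLINE_WINDOW] if windows is None else windows
    fits, behavior = fit_session_behavior(session.trials)

    needed_epochs = tuple({window_epoch_name(w) for w in windows})
    tuning = fit_session_tuning(
        session,
        epochs=needed_epochs,
        n_boot=n_boot_tuning,
        criterion_deg=criterion_deg,
        seed=rng,
        area=area,
    )
    deltas: dict[str, list] = {}
    for window in windows:
        pds = significant_pds(tuning[window_epoch_name(window)])
        per_window = []
        for group in GROUPS:
            if not pds:
                per_window.append(None)
                continue
            per_window.append(
                group_rate_difference(
                    session, pds, group, window, n_boot=n_boot_delta, seed=rng
                )
            )
        deltas[window.name] = per_window
    return SessionAnalysis(
        session_id=session.session_id,
        behavior_fits=fits,
        behavior=behavior,
        tuning=tuning,
        deltas=deltas,
    )


def run_study_regression(
    sessions: list[Session],
    windows: list[EpochWindow] | None = None,
    n_boot_tuning: int = 200,
    n_boot_delta: int = 200,
    criterion_deg: float = 45.0,
    seed=0,
    area: str | None = "PMd",
):
    """Analyze every session and regress group deltas on behavioral deltas.

    Returns ``(analyses, regressions, table)`` where ``regressions`` maps
    (window name, group) -> RegressionResult (or None on failure) and
    ``table`` is the per-session summary used by the subsampling analysis.
    """
    windows = [HEADLINE_WINDOW] if windows is None else windows
    ss = np.random.SeedSequence(seed if isinstance(seed, int) else 0)
    children = ss.spawn(len(sessions))
    analyses = [
        analyze_session(
            s,
            windows=windows,
            n_boot_tuning=n_boot_tuning,
            n_boot_delta=n_boot_delta,
            criterion_deg=criterion_deg,
            seed=np.random.default_rng(child),
            area=area,
        )
        for s, child in zip(sessions, children)
    ]
    behavior = {a.session_id: a.behavior for a in analyses}
    regressions: dict[tuple[str, str], RegressionResult | None] = {}
    for window in windows:
        per = [d for a in analyses for d in a.deltas.get(window.name, [])]
        for group in GROUPS:
            try:
                regressions[(window.name, group)] = uncertainty_activity_regression(
                    per, behavior, group, window.name
                )
            except ValueError:
                regressions[(window.name, group)] = None

    rows = []
    headline = windows[0].name
    for a in analyses:
        od = next(
            (d for d in a.deltas.get(headline, []) if d is not None and d.group == "OD"),
            None,
        )
        rows.append(
            dict(
                session_id=a.session_id,
                od_delta=od.delta if od is not None else math.nan,
                delta_behavioral_uncertainty=a.behavior.delta_behavioral_uncertainty,
                delta_cue_weighting=a.behavior.delta_cue_weighting,
                w_low=a.behavior_fits.get("low").slope if "low" in a.behavior_fits else math.nan,
                w_high=a.behavior_fits.get("high").slope if "high" in a.behavior_fits else math.nan,
            )
        )
    return analyses, regressions, pd.DataFrame(rows)


def run_study_decoding(
    sessions: list[Session],
    n_boot_tuning: int = 200,
    criterion_deg: float = 45.0,
    inclusion_threshold: float = 0.5,
    seed=0,
    area: str | None = "PMd",
):
    """Decode every session from center-out delay-period PDs.

    Returns ``(all_results, comparisons)`` where ``comparisons`` maps window
    name -> (mean low-minus-high performance difference, p, n sessions).
    """
    ss = np.random.SeedSequence(seed if isinstance(seed, int) else 0)
    children = ss.spawn(len(sessions))
    all_results: list[DecodeResult] = []
    for sess, child in zip(sessions, children):
        tuning = fit_session_tuning(
            sess,
            epochs=("delay",),
            n_boot=n_boot_tuning,
            criterion_deg=criterion_deg,
            seed=np.random.default_rng(child),
            area=area,
        )
        pds = significant_pds(tuning["delay"])
        if not pds:
            continue
        all_results.extend(
            decode_session(sess, pds, inclusion_threshold=inclusion_threshold)
        )
    comparisons = {}
    for wname in {r.window.name for r in all_results}:
        try:
            comparisons[wname] = compare_conditions(all_results, wname)
        except ValueError:
            comparisons[wname] = None
    return all_results, comparisons
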