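"""Single-trial reach-direction decoding from PD-binned population activity.

Neurons are assigned to sixteen 22.5-degree bins by their center-out
(zero-uncertainty) preferred direction.  On each trial the baseline-
subtracted rates are averaged within bins and a cosine
``a + b cos(phi - phi0)`` is least-squares fit to the 16-point profile over
the bin centers; its peak ``phi0`` is the decoded direction.  Performance for
a condition is one minus the circular variance of the decode errors —
equivalently the mean resultant length of the error sample — so 1 is perfect
decoding and 0 chance level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .circular import circ_summary, wrap_deg
from .session_io import EpochWindow, Session
from .population import windowed_rates

__all__ = [
    "DecodeResult",
    "N_BINS",
    "build_pd_bins",
    "bin_centers",
    "decode_trial",
    "decoder_performance",
    "decode_session",
    "compare_conditions",
    "default_decode_windows",
]

N_BINS = 16
BIN_WIDTH = 360.0 / N_BINS
MIN_OCCUPIED_BINS = 8
AMPLITUDE_TOL = 1e-9


@dataclass
class DecodeResult:
    """Decoder output for one session x window x condition."""

    session_id: str
    window: EpochWindow
    condition: str
    decoded: np.ndarray        # degrees per trial, NaN when undecodable
    errors: np.ndarray         # wrap(decoded - reach), NaN when undecodable
    performance: float         # 1 - circular variance of errors, in [0, 1]
    n_trials: int
    included: bool = True


def build_pd_bins(pds) -> np.ndarray:
    """Assign PDs (degrees) to the 16 decoder bins.

    Bin b covers [-180 + 22.5 b, -180 + 22.5 (b + 1)); the canonical-range
    upper endpoint +180 wraps into bin 0.
    """
    p = wrap_deg(np.asarray(pds, dtype=float))
    bins = np.floor((p + 180.0) / BIN_WIDTH).astype(int)
    return np.where(bins == N_BINS, 0, bins)


def bin_centers() -> np.ndarray:
    """Center angle of each decoder bin, degrees."""
    return -180.0 + BIN_WIDTH * (np.arange(N_BINS) + 0.5)


def decode_trial(bin_profile) -> float:
    """Peak of the least-squares cosine through a 16-bin rate profile.

    Empty bins are NaN and excluded from the fit; at least 8 occupied bins
    are required.  Returns NaN (undecodable / undefined) when occupancy or
    cosine amplitude is insufficient.
    """
    prof = np.asarray(bin_profile, dtype=float)
    if prof.shape != (N_BINS,):
        raise ValueError(f"bin profile must have length {N_BINS}")
    ok = np.isfinite(prof)
    if ok.sum() < MIN_OCCUPIED_BINS:
        return math.nan
    phi = np.radians(bin_centers()[ok])
    X = np.column_stack([np.ones(ok.sum()), np.cos(phi), np.sin(phi)])
    coef, *_ = np.linalg.lstsq(X, prof[ok], rcond=None)
    _, c1, c2 = coef
    if math.hypot(c1, c2) < AMPLITUDE_TOL:
        return math.nan
    return wrap_deg(math.degrees(math.atan2(c2, c1)))


def decoder_performance(errors) -> float:
    """One minus the circular variance of the (defined) decode errors.

    Identical to the mean resultant length R of the error sample.
    """
    e = np.asarray(errors, dtype=float)
    e = e[np.isfinite(e)]
    if e.size == 0:
        raise ValueError("no defined decode errors")
    return circ_summary(e).resultant_length


def default_decode_windows(step_ms: float = 200.0) -> list[EpochWindow]:
    """Four 200 ms windows spanning target appearance to movement.

    Three consecutive target-aligned windows cover the visual and delay
    periods; the fourth is re-aligned to movement onset.
    """
    return [
        EpochWindow("decode_0", "target_on", 0.0, step_ms),
        EpochWindow("decode_1", "target_on", step_ms, 2 * step_ms),
        EpochWindow("decode_2", "target_on", 2 * step_ms, 3 * step_ms),
        EpochWindow("decode_move", "move_on", 0.0, step_ms),
    ]


def decode_session(
    session: Session,
    center_out_pds: dict[str, float],
    windows: list[EpochWindow] | None = None,
    inclusion_threshold: float = 0.5,
    conditions: tuple[str, ...] = ("low", "high"),
) -> list[DecodeResult]:
    """Decode every uncertainty trial in each window and score by condition.

    Binning always uses PDs estimated from the zero-uncertainty center-out
    block.  The session-wide ``included`` flag requires the low-uncertainty
    performance to exceed ``inclusion_threshold`` in every window (sessions
    that cannot decode easy trials are uninformative about the condition
    contrast).
    """
    if not center_out_pds:
        raise ValueError("center-out PDs required")
    windows = default_decode_windows() if windows is None else windows
    neuron_ids = sorted(center_out_pds.keys())
    bins = build_pd_bins([center_out_pds[n] for n in neuron_ids])

    results = []
    for window in windows:
        for cond in conditions:
            trials = session.trials[
                (session.trials["block"] == "uncertainty")
                & (session.trials["condition"] == cond)
            ]
            if trials.empty:
                raise ValueError(f"condition {cond!r} missing from session")
            rates = windowed_rates(
                session.spikes, trials, window, neuron_ids, baseline_subtract=True
            ).to_numpy()
            profiles = np.full((len(trials), N_BINS), np.nan)
            for b in range(N_BINS):
                cols = bins == b
                if cols.any():
                    profiles[:, b] = rates[:, cols].mean(axis=1)
            decoded = np.array([decode_trial(p) for p in profiles])
            reach = trials["reach_deg"].to_numpy(dtype=float)
            ok = np.isfinite(decoded)
            errors = np.full(len(trials), np.nan)
            if ok.any():
                errors[ok] = wrap_deg(decoded[ok] - reach[ok])
                perf = decoder_performance(errors)
            else:
                perf = math.nan  # no decodable trial in this condition

            results.append(
                DecodeResult(
                    session_id=session.session_id,
                    window=window,
                    condition=cond,
                    decoded=decoded,
                    errors=errors,
                    performance=perf,
                    n_trials=len(trials),
                )
            )
    # session-wide inclusion from low-uncertainty performance
    low_perfs = [r.performance for r in results if r.condition == "low"]
    included = (
        bool(np.all(np.isfinite(low_perfs)) and min(low_perfs) > inclusion_threshold)
        if low_perfs
        else False
    )
    for r in results:
        r.included = included
    return results


def compare_conditions(results: list[DecodeResult], window_name: str):
    """Paired t-test of low-vs-high decoder performance across sessions.

    Only sessions passing the inclusion rule contribute.  Returns
    ``(mean_difference, p_value, n_sessions)`` where the difference is
    low minus high.
    """
    per_session: dict[str, dict[str, float]] = {}
    for r in results:
        if r.window.name != window_name or not r.included:
            continue
        if not math.isfinite(r.performance):
            continue
        per_session.setdefault(r.session_id, {})[r.condition] = r.performance
    diffs = [
        v["low"] - v["high"] for v in per_session.values() if "low" in v and "high" in v
    ]
    if len(diffs) < 3:
        raise ValueError("need at least 3 included sessions with both conditions")
    diffs = np.asarray(diffs)
    if np.allclose(diffs, diffs[0]):
        p = 1.0 if abs(diffs[0]) < 1e-12 else 0.0
    else:
        p = float(stats.ttest_1samp(diffs, 0.0).pvalue)
    return float(diffs.mean()), p, len(diffs)
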