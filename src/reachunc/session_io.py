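"""Session data layout: readers, writers and validation.

A *session* is one recording day: a trials table and a spike-events table.
Trials come in two blocks — a ``center_out`` block of reaches to eight
well-specified targets (``zero`` uncertainty condition) and an
``uncertainty`` block where targets are drawn from a von Mises prior and cued
by a fan of noisy lines (``low`` / ``high`` uncertainty conditions).

On disk everything is plain CSV:

``trials.csv``
    session_id, trial_id, block, condition, prior_mean_deg, cue_lines_deg
    (semicolon-joined), cue_centroid_deg, target_deg, reach_deg,
    t_target_on_s, t_go_s, t_move_on_s, reaction_time_s, peak_speed_cms
``spikes.csv``
    trial_id, neuron_id, t_s  (seconds relative to target onset; negative
    times are pre-target baseline)
``neurons.csv`` (synthetic ground truth, optional)
    neuron_id, area, pd_deg, baseline_hz, beta_visual, beta_delay,
    beta_movement, od_gain
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .circular import circ_summary, wrap_deg

__all__ = [
    "EpochWindow",
    "Session",
    "VISUAL",
    "DELAY",
    "MOVEMENT",
    "BASELINE",
    "read_session",
    "write_session",
    "write_results",
    "validate_trials",
    "validate_spikes",
]

TRIAL_COLUMNS = [
    "session_id",
    "trial_id",
    "block",
    "condition",
    "prior_mean_deg",
    "cue_lines_deg",
    "cue_centroid_deg",
    "target_deg",
    "reach_deg",
    "t_target_on_s",
    "t_go_s",
    "t_move_on_s",
    "reaction_time_s",
    "peak_speed_cms",
]
SPIKE_COLUMNS = ["trial_id", "neuron_id", "t_s"]

BLOCKS = {"center_out", "uncertainty"}
CONDITIONS = {"zero", "low", "high"}


@dataclass(frozen=True)
class EpochWindow:
    """Half-open analysis window [start_ms, end_ms) on one of two alignments.

    ``target_on`` windows are measured from target appearance, ``move_on``
    windows from reach onset.
    """

    name: str
    alignment: Literal["target_on", "move_on"]
    start_ms: float
    end_ms: float

    def __post_init__(self):
        if self.start_ms >= self.end_ms:
            raise ValueError("EpochWindow requires start_ms < end_ms")
        if self.alignment not in ("target_on", "move_on"):
            raise ValueError(f"unknown alignment {self.alignment!r}")

    @property
    def duration_s(self) -> float:
        return (self.end_ms - self.start_ms) / 1000.0


# canonical epochs: an early visual burst, sustained delay planning, and
# peri-movement activity; baseline precedes target onset
VISUAL = EpochWindow("visual", "target_on", 50.0, 250.0)
DELAY = EpochWindow("delay", "target_on", 300.0, 700.0)
MOVEMENT = EpochWindow("movement", "move_on", 0.0, 200.0)
BASELINE = EpochWindow("baseline", "target_on", -300.0, 0.0)

EPOCHS = {e.name: e for e in (VISUAL, DELAY, MOVEMENT, BASELINE)}


@dataclass
class Session:
    """One recorded session: trials, spikes and optional neuron ground truth."""

    session_id: str
    trials: pd.DataFrame
    spikes: pd.DataFrame
    neurons: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def block(self, name: str) -> pd.DataFrame:
        return self.trials[self.trials["block"] == name]

    def condition(self, name: str) -> pd.DataFrame:
        return self.trials[self.trials["condition"] == name]


class SessionFormatError(ValueError):
    """Raised when a session file violates the documented layout."""


def _require_columns(df: pd.DataFrame, required, what: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SessionFormatError(f"{what} is missing columns: {missing}")


def validate_trials(trials: pd.DataFrame) -> None:
    """Check the trial-table invariants, reporting offending row numbers."""
    _require_columns(trials, TRIAL_COLUMNS, "trials table")
    bad_block = ~trials["block"].isin(BLOCKS)
    if bad_block.any():
        rows = trials.index[bad_block].tolist()[:5]
        raise SessionFormatError(f"unknown block label at rows {rows}")
    bad_cond = ~trials["condition"].isin(CONDITIONS)
    if bad_cond.any():
        rows = trials.index[bad_cond].tolist()[:5]
        raise SessionFormatError(f"unknown condition label at rows {rows}")
    zero_mismatch = (trials["condition"] == "zero") != (
        trials["block"] == "center_out"
    )
    if zero_mismatch.any():
        rows = trials.index[zero_mismatch].tolist()[:5]
        raise SessionFormatError(
            f"condition 'zero' must coincide with block 'center_out' (rows {rows})"
        )
    for col in ("target_deg", "reach_deg"):
        vals = trials[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise SessionFormatError(f"non-finite angle in column {col}")
        if np.any(vals <= -180.0) or np.any(vals > 180.0):
            rows = trials.index[(vals <= -180.0) | (vals > 180.0)].tolist()[:5]
            raise SessionFormatError(
                f"angle out of canonical range (-180, 180] in {col} at rows {rows}"
            )
    order_bad = ~(
        (trials["t_target_on_s"] < trials["t_go_s"])
        & (trials["t_go_s"] < trials["t_move_on_s"])
    )
    if order_bad.any():
        rows = trials.index[order_bad].tolist()[:5]
        raise SessionFormatError(
            f"event times must satisfy target_on < go < move_on (rows {rows})"
        )
    if trials["trial_id"].duplicated().any():
        raise SessionFormatError("duplicate trial_id")
    # centroid consistency for trials with cue lines
    for idx, row in trials.iterrows():
        lines = parse_cue_lines(row["cue_lines_deg"])
        if lines.size:
            centroid = circ_summary(lines).mean
            if abs(wrap_deg(centroid - float(row["cue_centroid_deg"]))) > 0.01:
                raise SessionFormatError(
                    f"cue_centroid_deg disagrees with circular mean of "
                    f"cue_lines_deg at row {idx}"
                )


def validate_spikes(spikes: pd.DataFrame, trials: pd.DataFrame) -> None:
    """Referential integrity: every spike must point at an existing trial."""
    _require_columns(spikes, SPIKE_COLUMNS, "spikes table")
    known = set(trials["trial_id"].to_numpy())
    orphan = ~spikes["trial_id"].isin(known)
    if orphan.any():
        rows = spikes.index[orphan].tolist()[:5]
        raise SessionFormatError(
            f"spike rows reference unknown trial_id (rows {rows})"
        )
    if not np.all(np.isfinite(spikes["t_s"].to_numpy(dtype=float))):
        raise SessionFormatError("non-finite spike time")


def parse_cue_lines(value) -> np.ndarray:
    """Decode the semicolon-joined cue-line angles; empty/NaN means no lines."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.array([])
    s = str(value).strip()
    if not s:
        return np.array([])
    return np.array([float(x) for x in s.split(";")])


def format_cue_lines(lines) -> str:
    return ";".join(f"{float(x):.6g}" for x in np.atleast_1d(lines)) if len(lines) else ""


def read_session(
    trials_path, spikes_path, neurons_path=None, validate: bool = True
) -> Session:
    """Load a session from CSV, validating layout and referential integrity."""
    trials = pd.read_csv(trials_path, comment="#", keep_default_na=True)
    spikes = pd.read_csv(spikes_path, comment="#")
    if spikes.empty and list(spikes.columns) != SPIKE_COLUMNS:
        spikes = pd.DataFrame(columns=SPIKE_COLUMNS)
    if "cue_lines_deg" in trials.columns:
        trials["cue_lines_deg"] = trials["cue_lines_deg"].fillna("")
    if validate:
        validate_trials(trials)
        validate_spikes(spikes, trials)
    neurons = None
    if neurons_path is not None:
        neurons = pd.read_csv(neurons_path, comment="#")
    session_id = str(trials["session_id"].iloc[0]) if len(trials) else "empty"
    return Session(session_id=session_id, trials=trials, spikes=spikes, neurons=neurons)


def write_session(session: Session, out_dir, prefix: str = "") -> dict:
    """Write trials/spikes (and neurons, when present) as CSV; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    trials_path = out / f"{prefix}trials.csv"
    session.trials.to_csv(trials_path, index=False)
    paths["trials"] = trials_path
    spikes_path = out / f"{prefix}spikes.csv"
    session.spikes.to_csv(spikes_path, index=False)
    paths["spikes"] = spikes_path
    if session.neurons is not None:
        neurons_path = out / f"{prefix}neurons.csv"
        session.neurons.to_csv(neurons_path, index=False)
        paths["neurons"] = neurons_path
    return paths


def _config_hash(meta: dict) -> str:
    return hashlib.sha256(
        json.dumps(meta, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_results(results: pd.DataFrame, path, meta: dict | None = None) -> Path:
    """Write a results table with deterministic layout and embedded metadata.

    Columns keep their incoming order, floats are rendered at six significant
    digits, and run metadata (seed, config hash, package version) is embedded
    as ``#``-prefixed header lines so the file remains a valid CSV.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = dict(meta or {})
    from . import __version__

    meta.setdefault("version", __version__)
    meta["config_hash"] = _config_hash(meta)
    with open(path, "w") as fh:
        for key in sorted(meta):
            fh.write(f"# {key}: {meta[key]}\n")
        results.to_csv(fh, index=False, float_format="%.6g")
    return path


def move_aligned_times(spikes: pd.DataFrame, trials: pd.DataFrame) -> np.ndarray:
    """Spike times re-referenced to movement onset.

    Spike times are stored relative to target onset; movement-aligned
    analyses subtract the per-trial latency ``t_move_on - t_target_on``.
    """
    latency = (trials["t_move_on_s"] - trials["t_target_on_s"]).to_numpy()
    lat_by_trial = pd.Series(latency, index=trials["trial_id"].to_numpy())
    return spikes["t_s"].to_numpy() - lat_by_trial.reindex(
        spikes["trial_id"].to_numpy()
    ).to_numpy()
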