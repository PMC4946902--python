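"""Directional tuning: epoch spike counts, Poisson-GLM cosine fits, bootstrap
preferred-direction significance.

Each neuron's trial firing rate in an epoch is modeled as

    lambda = exp(alpha + beta * cos(theta - theta_star))

where ``theta`` is the reach direction, ``theta_star`` the preferred
direction (PD), ``alpha`` the log baseline rate (log spikes/s) and
``beta >= 0`` the modulation depth.  The fit is a Poisson GLM on the
linearized parameterization ``alpha + b1 cos(theta) + b2 sin(theta)`` with
the log epoch duration as exposure offset; ``beta = hypot(b1, b2)`` and
``theta_star = atan2(b2, b1)``.  The log-likelihood is concave in
``(alpha, b1, b2)`` so a damped Newton solve converges globally.

PD significance follows a trial-resampling bootstrap: a neuron is tuned when
95% of bootstrap PDs fall within ``criterion_deg`` (default 45, relaxable to
90 for low-count datasets) of the circular mean of the bootstrap sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import circ_summary, circular_distance_deg, wrap_deg
from .session_io import EpochWindow

__all__ = [
    "EpochCounts",
    "TuningFit",
    "epoch_spike_counts",
    "fit_poisson_tuning",
    "bootstrap_pd_significance",
    "tuned_fraction",
]


@dataclass
class EpochCounts:
    """Per-trial spike counts for one neuron in one epoch."""

    neuron_id: str
    epoch: EpochWindow
    counts: np.ndarray      # nonnegative integers, one per trial
    durations: np.ndarray   # seconds, one per trial
    directions: np.ndarray  # reach direction, degrees, one per trial

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.directions = np.asarray(self.directions, dtype=float)
        if not (len(self.counts) == len(self.durations) == len(self.directions)):
            raise ValueError("counts, durations and directions must be paired")
        if np.any(self.durations <= 0):
            raise ValueError("durations must be positive")


@dataclass
class TuningFit:
    """Cosine-tuning parameters for one neuron in one epoch."""

    neuron_id: str
    epoch: str
    alpha: float                 # log rate offset, log spikes/s
    beta: float                  # modulation depth >= 0
    pd: float                    # preferred direction theta*, degrees
    loglik: float
    converged: bool
    stable: bool                 # False when beta ~ 0 (PD direction meaningless)
    pd_boot: np.ndarray | None = None
    significant: bool | None = None
    criterion_deg: float | None = None
    n_boot_failed: int = 0
    session_id: str | None = None


def _aligned_times(spikes: pd.DataFrame, trials: pd.DataFrame, epoch: EpochWindow):
    t = spikes["t_s"].to_numpy(dtype=float)
    if epoch.alignment == "move_on":
        move = trials["t_move_on_s"].to_numpy() - trials["t_target_on_s"].to_numpy()
        if np.any(~np.isfinite(move)):
            raise ValueError("movement-aligned epoch on trial without t_move_on")
        lat = pd.Series(move, index=trials["trial_id"].to_numpy())
        t = t - lat.reindex(spikes["trial_id"].to_numpy()).to_numpy()
    return t


def epoch_spike_counts(
    spikes: pd.DataFrame, trials: pd.DataFrame, epoch: EpochWindow
) -> dict[str, EpochCounts]:
    """Spike counts per neuron per trial within a half-open epoch window.

    Returns a mapping neuron_id -> :class:`EpochCounts` whose trial order
    follows the ``trials`` table.  Every neuron appearing in ``spikes`` is
    represented; trials without spikes contribute zero counts.
    """
    t = _aligned_times(spikes, trials, epoch)
    lo, hi = epoch.start_ms / 1000.0, epoch.end_ms / 1000.0
    inside = (t >= lo) & (t < hi)
    sub = spikes.loc[inside]

    trial_ids = trials["trial_id"].to_numpy()
    sub = sub[sub["trial_id"].isin(trial_ids)]
    trial_pos = pd.Series(np.arange(len(trial_ids)), index=trial_ids)
    neuron_ids = np.asarray(sorted(spikes["neuron_id"].unique()))
    neuron_pos = pd.Series(np.arange(len(neuron_ids)), index=neuron_ids)

    counts = np.zeros((len(trial_ids), len(neuron_ids)))
    if len(sub):
        ti = trial_pos.reindex(sub["trial_id"].to_numpy()).to_numpy()
        ni = neuron_pos.reindex(sub["neuron_id"].to_numpy()).to_numpy()
        np.add.at(counts, (ti.astype(int), ni.astype(int)), 1.0)

    durations = np.full(len(trial_ids), epoch.duration_s)
    directions = trials["reach_deg"].to_numpy(dtype=float)
    return {
        str(nid): EpochCounts(
            neuron_id=str(nid),
            epoch=epoch,
            counts=counts[:, j],
            durations=durations,
            directions=directions,
        )
        for j, nid in enumerate(neuron_ids)
    }


def _design(directions_deg: np.ndarray) -> np.ndarray:
    th = np.radians(directions_deg)
    return np.column_stack([np.ones_like(th), np.cos(th), np.sin(th)])


def _newton_poisson(X, y, log_dur, tol=1e-8, max_iter=100):
    """Damped Newton for the Poisson log-likelihood; concave, globally convergent."""
    mean_rate = max(y.sum() / np.exp(log_dur).sum(), 1e-8)
    beta = np.array([math.log(mean_rate), 0.0, 0.0])
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta + log_dur
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        grad = X.T @ (y - mu)
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        H = (X * mu[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # backtracking keeps the concave objective increasing
        t = 1.0
        ll_cur = float(y @ eta - mu.sum())
        for _ in range(30):
            cand = beta + t * step
            eta_c = np.clip(X @ cand + log_dur, -30.0, 30.0)
            ll_new = float(y @ eta_c - np.exp(eta_c).sum())
            if ll_new >= ll_cur - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        if abs(ll_new - ll_old) < 1e-12 and np.linalg.norm(grad) < 1e-6:
            converged = True
            break
        ll_old = ll_new
    eta = np.clip(X @ beta + log_dur, -30.0, 30.0)
    ll = float(y @ eta - np.exp(eta).sum())
    return beta, ll, converged


BETA_STABLE_TOL = 1e-6


def fit_poisson_tuning(data: EpochCounts, min_trials: int = 8) -> TuningFit:
    """Maximum-likelihood cosine tuning fit for one neuron and epoch."""
    n = len(data.counts)
    if n < min_trials:
        raise ValueError(f"need at least {min_trials} trials, got {n}")
    distinct = np.unique(np.round(wrap_deg(data.directions), 6))
    if distinct.size < 3:
        raise ValueError("need at least 3 distinct reach directions")
    X = _design(data.directions)
    log_dur = np.log(data.durations)
    coef, ll, converged = _newton_poisson(X, data.counts, log_dur)
    alpha, b1, b2 = coef
    beta = math.hypot(b1, b2)
    stable = beta > BETA_STABLE_TOL
    pd_deg = wrap_deg(math.degrees(math.atan2(b2, b1))) if stable else math.nan
    if data.counts.sum() == 0:
        stable = False
        converged = True  # degenerate but well understood: alpha -> -inf
    return TuningFit(
        neuron_id=data.neuron_id,
        epoch=data.epoch.name,
        alpha=float(alpha),
        beta=float(beta),
        pd=pd_deg,
        loglik=ll,
        converged=bool(converged),
        stable=bool(stable),
    )


def _newton_poisson_batch(Xb, yb, log_dur_b, n_iter=25):
    """Vectorized Newton across B bootstrap resamples (same trial count)."""
    B, n, _ = Xb.shape
    mean_rate = np.maximum(yb.sum(axis=1) / np.exp(log_dur_b).sum(axis=1), 1e-8)
    beta = np.zeros((B, 3))
    beta[:, 0] = np.log(mean_rate)
    for _ in range(n_iter):
        eta = np.clip(np.einsum("bnk,bk->bn", Xb, beta) + log_dur_b, -30.0, 30.0)
        mu = np.exp(eta)
        grad = np.einsum("bnk,bn->bk", Xb, yb - mu)
        H = np.einsum("bnk,bn,bnl->bkl", Xb, mu, Xb)
        H += 1e-10 * np.eye(3)[None]
        try:
            step = np.linalg.solve(H, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack([np.linalg.lstsq(h, g, rcond=None)[0] for h, g in zip(H, grad)])
        np.clip(step, -5.0, 5.0, out=step)  # damping for early iterations
        beta += step
        if np.max(np.abs(step)) < 1e-10:
            break
    grad_norm = np.linalg.norm(grad, axis=1)
    return beta, grad_norm


def bootstrap_pd_significance(
    data: EpochCounts,
    n_boot: int = 1000,
    criterion_deg: float = 45.0,
    seed=0,
) -> TuningFit:
    """Trial-resampling bootstrap test of preferred-direction stability.

    ``n_boot`` resamples (with replacement, same size) are refit; the neuron
    is significantly tuned when at least 95% of bootstrap PDs lie within
    ``criterion_deg`` of the circular mean of the bootstrap PD sample.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    fit = fit_poisson_tuning(data)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = len(data.counts)
    idx = rng.integers(0, n, size=(n_boot, n))
    X = _design(data.directions)
    Xb = X[idx]
    yb = data.counts[idx]
    log_dur_b = np.log(data.durations)[idx]
    coef, grad_norm = _newton_poisson_batch(Xb, yb, log_dur_b)
    ok = grad_norm < 1e-4
    n_failed = int((~ok).sum())
    if n_failed > 0.10 * n_boot:
        fit.significant = False
        fit.criterion_deg = criterion_deg
        fit.n_boot_failed = n_failed
        fit.converged = False
        return fit
    pd_boot = wrap_deg(np.degrees(np.arctan2(coef[ok, 2], coef[ok, 1])))
    boot_mean = circ_summary(pd_boot).mean
    within = circular_distance_deg(pd_boot, boot_mean) <= criterion_deg
    fit.pd_boot = pd_boot
    fit.significant = bool(np.mean(within) >= 0.95) and fit.stable
    fit.criterion_deg = criterion_deg
    fit.n_boot_failed = n_failed
    return fit


def tuned_fraction(fits, epoch: str | None = None) -> float:
    """Percentage of fit-able neurons flagged significantly tuned."""
    pool = [f for f in fits if epoch is None or f.epoch == epoch]
    if not pool:
        raise ValueError("no fits supplied")
    epochs = {f.epoch for f in pool}
    if len(epochs) > 1:
        raise ValueError(f"fits span multiple epochs: {sorted(epochs)}")
    return 100.0 * sum(bool(f.significant) for f in pool) / len(pool)
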