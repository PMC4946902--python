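"""Bayesian cue-integration fits to reach behavior.

On uncertainty trials the observer knows two things about the target: the
session-constant mean of the target distribution (the prior, mean ``mu1``)
and the centroid of the noisy cue lines shown on that trial (the likelihood,
mean ``mu2``).  Modeling both as von Mises distributions, the mean of their
product is

    mu3 = mu1 + atan2(k2 sin(mu2 - mu1), k1 + k2 cos(mu2 - mu1))

and for moderate offsets this is well approximated by the line

    mu3 ~= mu1 + w (mu2 - mu1),    w = k2 / (k1 + k2)

The slope ``w`` — the *cue weighting* — is 1 under pure reliance on the
visual cue and 0 under pure reliance on the prior.  Only the ratio
``r = k1/k2`` is identifiable from reach directions, so the fit searches over
``r`` to minimize the squared wrapped residuals between predicted and actual
reaches.  Two session-level metrics summarize each uncertainty condition
pair: ``delta cue weighting = w_high - w_low`` and ``delta behavioral
uncertainty = dispersion_high - dispersion_low`` (angular dispersion of the
fit residuals, degrees).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .circular import circ_summary, wrap_deg

__all__ = [
    "BehaviorFit",
    "SessionBehaviorSummary",
    "fit_cue_weighting",
    "behavioral_uncertainty",
    "session_deltas",
    "fit_session_behavior",
    "predict_reach",
]

LOG_RATIO_BOUNDS = (-6.0, 6.0)
_GRID_POINTS = 1000
MIN_TRIALS = 10


@dataclass
class BehaviorFit:
    """Cue-weighting fit for one uncertainty condition within a session."""

    condition: str
    ratio: float            # r = k1/k2 (prior/likelihood concentration)
    slope: float            # w = 1/(1 + r), in [0, 1]
    sse: float              # sum of squared wrapped residuals, deg^2
    residuals: np.ndarray   # reach - predicted mu3, wrapped to (-180, 180]
    dispersion: float       # angular dispersion of residuals, degrees
    n_trials: int
    at_bound: bool = False          # ratio pinned at a search bound
    identifiable: bool = True       # False when all centroids coincide
    session_id: str | None = None


@dataclass(frozen=True)
class SessionBehaviorSummary:
    """High-minus-low behavioral deltas for one session."""

    session_id: str | None
    delta_cue_weighting: float
    delta_behavioral_uncertainty: float


def predict_reach(prior_mean: float, centroids, ratio: float) -> np.ndarray:
    """Model-predicted reach directions mu3 for a prior/likelihood ratio.

    Uses the exact product-mean expression; the ratio enters through
    ``k1 = ratio, k2 = 1`` since only ``k1/k2`` matters.
    """
    cen = np.atleast_1d(np.asarray(centroids, dtype=float))
    d = np.radians(wrap_deg(cen - prior_mean))
    offset = np.arctan2(np.sin(d), ratio + np.cos(d))
    return wrap_deg(prior_mean + np.degrees(offset))


def _objective(log_r: float, prior_mean, centroids, reaches) -> float:
    pred = predict_reach(prior_mean, centroids, math.exp(log_r))
    resid = wrap_deg(reaches - pred)
    return float(np.dot(resid, resid))


def fit_cue_weighting(
    prior_mean: float,
    cue_centroids,
    reaches,
    condition: str = "",
    min_trials: int = MIN_TRIALS,
    session_id: str | None = None,
) -> BehaviorFit:
    """Fit the concentration ratio r = k1/k2 by least squares on reaches.

    A dense grid over ``log r`` on [-6, 6] is refined by golden-section
    search; this avoids the local minima and infinite-ratio degeneracies of
    an unconstrained 1-D optimization.  Slope ``w = 1/(1+r)`` plus wrapped
    residuals and their angular dispersion populate the returned fit.
    """
    centroids = np.asarray(cue_centroids, dtype=float)
    reaches = np.asarray(reaches, dtype=float)
    if centroids.shape != reaches.shape:
        raise ValueError("cue_centroids and reaches must be paired")
    n = centroids.size
    if n < min_trials:
        raise ValueError(f"need at least {min_trials} trials, got {n}")

    spread = circ_summary(centroids).resultant_length
    identifiable = spread < 1.0 - 1e-12

    lo, hi = LOG_RATIO_BOUNDS
    grid = np.linspace(lo, hi, _GRID_POINTS)
    losses = np.array([_objective(g, prior_mean, centroids, reaches) for g in grid])
    k = int(np.argmin(losses))

    # golden-section refinement within the bracketing grid cells
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, _GRID_POINTS - 1)]
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc = _objective(c, prior_mean, centroids, reaches)
    fd = _objective(d, prior_mean, centroids, reaches)
    for _ in range(60):
        if b - a < 1e-10:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _objective(c, prior_mean, centroids, reaches)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _objective(d, prior_mean, centroids, reaches)
    log_r = (a + b) / 2.0
    ratio = math.exp(log_r)
    at_bound = log_r <= lo + 1e-6 or log_r >= hi - 1e-6

    pred = predict_reach(prior_mean, centroids, ratio)
    residuals = wrap_deg(reaches - pred)
    sse = float(np.dot(residuals, residuals))
    dispersion = circ_summary(residuals).dispersion
    return BehaviorFit(
        condition=condition,
        ratio=ratio,
        slope=1.0 / (1.0 + ratio),
        sse=sse,
        residuals=residuals,
        dispersion=dispersion,
        n_trials=n,
        at_bound=at_bound,
        identifiable=identifiable,
        session_id=session_id,
    )


def behavioral_uncertainty(fit: BehaviorFit) -> float:
    """Angular dispersion (degrees) of the residual reach errors."""
    if fit.residuals is None or len(fit.residuals) == 0:
        raise ValueError("fit has no residuals")
    return circ_summary(fit.residuals).dispersion


def session_deltas(low: BehaviorFit, high: BehaviorFit) -> SessionBehaviorSummary:
    """High-minus-low deltas of cue weighting and behavioral uncertainty."""
    if low.session_id != high.session_id:
        raise ValueError("fits come from different sessions")
    return SessionBehaviorSummary(
        session_id=low.session_id,
        delta_cue_weighting=high.slope - low.slope,
        delta_behavioral_uncertainty=high.dispersion - low.dispersion,
    )


def fit_session_behavior(trials) -> tuple[dict, SessionBehaviorSummary]:
    """Fit both uncertainty conditions of one session's trial table.

    Returns ``({'low': fit, 'high': fit}, deltas)``.  Raises when the session
    has no uncertainty trials.
    """
    unc = trials[trials["block"] == "uncertainty"]
    if unc.empty:
        raise ValueError("no uncertainty trials in session")
    session_id = str(trials["session_id"].iloc[0])
    fits = {}
    for cond in ("low", "high"):
        sub = unc[unc["condition"] == cond]
        if sub.empty:
            continue
        fits[cond] = fit_cue_weighting(
            float(sub["prior_mean_deg"].iloc[0]),
            sub["cue_centroid_deg"].to_numpy(dtype=float),
            sub["reach_deg"].to_numpy(dtype=float),
            condition=cond,
            session_id=session_id,
        )
    if "low" in fits and "high" in fits:
        deltas = session_deltas(fits["low"], fits["high"])
    else:
        deltas = SessionBehaviorSummary(session_id, math.nan, math.nan)
    return fits, deltas


def linear_approximation(prior_mean: float, centroids, ratio: float) -> np.ndarray:
    """First-order prediction mu1 + w (mu2 - mu1); valid for moderate offsets."""
    w = 1.0 / (1.0 + ratio)
    cen = np.atleast_1d(np.asarray(centroids, dtype=float))
    return wrap_deg(prior_mean + w * wrap_deg(cen - prior_mean))
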