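"""Proportional-hazards output layer: matrix-form partial likelihood.

The Cox partial log-likelihood

    pl(theta) = sum_{i : event_i = 1} ( theta_i - log sum_{j : t_j >= t_i} exp(theta_j) )

is evaluated through the risk-set indicator matrix ``R`` so the inner
conditional sum becomes one matrix product ``R . exp(theta)``, stabilized by
log-sum-exp.  Ties share a denominator (Breslow).  The analytic gradient in
``theta`` is what back-propagation starts from, and the Breslow baseline
hazard turns a fitted prognostic index into absolute survival probabilities
for the Brier score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data import RiskSetMatrix

__all__ = [
    "BaselineHazard",
    "partial_log_likelihood",
    "pll_gradient",
    "breslow_baseline",
]


def _check(theta: np.ndarray, R: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    theta = np.asarray(theta, dtype=float).ravel()
    event = np.asarray(event).ravel()
    n = theta.shape[0]
    if R.shape != (n, n) or event.shape[0] != n:
        raise ValueError(f"dimension mismatch: theta {n}, R {R.shape}, event {event.shape}")
    if event.sum() < 1:
        raise ValueError("partial likelihood undefined without any observed event")
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    return theta, R, event


def _row_logsumexp(theta: np.ndarray, R: np.ndarray) -> np.ndarray:
    # log(R @ exp(theta)) stabilized by a global shift: one matrix product.
    # Every row contains its own patient, so a row only underflows to zero
    # when all its members sit ~745 below the max theta; those rare rows are
    # recomputed with per-row stabilization.
    m = theta.max()
    s = R @ np.exp(theta - m)
    with np.errstate(divide="ignore"):
        lse = np.log(s) + m
    bad = ~np.isfinite(lse)
    if np.any(bad):
        lse[bad] = logsumexp(
            np.broadcast_to(theta, (int(bad.sum()), theta.shape[0])), axis=1, b=R[bad]
        )
    return lse


def partial_log_likelihood(
    theta: np.ndarray,
    risk: RiskSetMatrix | np.ndarray,
    event: np.ndarray,
    *,
    reduction: str = "sum",
) -> float:
    """Cox partial log-likelihood of a prognostic-index vector.

    Parameters
    ----------
    theta
        Log hazard ratio per patient.
    risk
        Risk-set matrix for the patients' observed times.
    event
        0/1 event indicators.
    reduction
        ``"sum"`` (the optimization objective) or ``"mean"`` (per-event mean,
        comparable across datasets of different size).
    """
    R = risk.R if isinstance(risk, RiskSetMatrix) else np.asarray(risk)
    theta, R, event = _check(theta, R, event)
    lse = _row_logsumexp(theta, R)
    terms = event * (theta - lse)
    total = float(terms.sum())
    if reduction == "mean":
        return total / float(event.sum())
    if reduction != "sum":
        raise ValueError(f"unknown reduction {reduction!r}")
    return total


def pll_gradient(
    theta: np.ndarray,
    risk: RiskSetMatrix | np.ndarray,
    event: np.ndarray,
) -> np.ndarray:
    """Analytic gradient of the partial log-likelihood in ``theta``.

    Equals ``event - P^T event`` where ``P[i, j]`` is patient ``j``'s softmax
    share of risk set ``i``; the entries always sum to zero (the likelihood
    is invariant to a constant shift of ``theta``).
    """
    R = risk.R if isinstance(risk, RiskSetMatrix) else np.asarray(risk)
    theta, R, event = _check(theta, R, event)
    lse = _row_logsumexp(theta, R)
    # clip at 0 before exponentiating: in-set entries satisfy theta_j <= lse_i
    # anyway, while out-of-set entries (zeroed by R) could overflow unclipped
    P = R * np.exp(np.minimum(theta[None, :] - lse[:, None], 0.0))
    return event - P.T @ event.astype(float)


@dataclass
class BaselineHazard:
    """Breslow cumulative baseline hazard as a right-continuous step function.

    ``cumulative_hazard[k]`` is ``H0`` at ``times[k]``; predicted survival for
    a patient with prognostic index ``theta`` is
    ``S(t) = exp(-H0(t) * exp(theta))``.
    """

    times: np.ndarray
    cumulative_hazard: np.ndarray

    def cumhaz_at(self, t: np.ndarray) -> np.ndarray:
        """H0 evaluated at arbitrary times (0 before the first event)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        padded = np.concatenate([[0.0], self.cumulative_hazard])
        return padded[idx]

    def survival(self, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
        """Survival matrix ``S[i, k] = exp(-H0(t_k) exp(theta_i))``."""
        H = self.cumhaz_at(t)
        return np.exp(-np.outer(np.exp(np.asarray(theta, dtype=float)), H))


def breslow_baseline(theta: np.ndarray, time: np.ndarray, event: np.ndarray) -> BaselineHazard:
    """Breslow estimator of the cumulative baseline hazard.

    At each distinct event time ``s`` the hazard increments by
    ``d_s / sum_{j : t_j >= s} exp(theta_j)`` with ``d_s`` the number of tied
    events at ``s``.  With ``theta = 0`` this is the Nelson-Aalen estimator.
    """
    theta = np.asarray(theta, dtype=float).ravel()
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event).ravel()
    if event.sum() < 1:
        raise ValueError("baseline hazard undefined without any observed event")
    event_times = np.unique(time[event == 1])
    risk_exp = np.exp(theta)
    increments = np.empty_like(event_times)
    for k, s in enumerate(event_times):
        d = int(((time == s) & (event == 1)).sum())
        denom = risk_exp[time >= s].sum()
        increments[k] = d / denom
    return BaselineHazard(times=event_times, cumulative_hazard=np.cumsum(increments))
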