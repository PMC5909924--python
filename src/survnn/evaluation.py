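"""Survival prediction accuracy metrics and the repeated-holdout harness.

Four complementary metrics are computed on a held-out test set:

* Harrell's concordance index — the fraction of comparable patient pairs
  whose predicted risk ordering matches their observed survival ordering.
* IPCW concordance — the same pair count reweighted by the inverse squared
  Kaplan-Meier probability of remaining uncensored, which removes the bias
  the plain C-index acquires when censoring correlates with risk.
* Log-rank p-value after dichotomizing patients at the median prognostic
  index into high- and low-risk groups.
* Integrated Brier score — time-averaged squared error between predicted
  survival probability and observed status, with IPCW weights for censored
  patients.

Kaplan-Meier estimation and the two-sample log-rank test are delegated to
lifelines; the concordance and Brier computations are implemented here
because their pair, tie and weight conventions are part of this package's
contract (and are cross-checked against independent implementations in the
test suite).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .coxph import BaselineHazard, breslow_baseline
from .data import SurvivalDataset, train_test_split
from .network import ModelSpec, TrainConfig, SurvivalNet, train

__all__ = [
    "EvaluationReport",
    "CensoringDistribution",
    "c_harrell",
    "c_ipcw",
    "logrank_dichotomized",
    "integrated_brier",
    "evaluate_model",
    "repeated_holdout",
    "reports_to_frame",
]


@dataclass
class EvaluationReport:
    """The four accuracy metrics for one model on one held-out split."""

    c_harrell: float
    c_ipcw: float
    logrank_p: float
    integrated_brier: float
    n_test: int
    n_events_test: int


class CensoringDistribution:
    """Kaplan-Meier estimate G(t) of the *censoring* survival function.

    Fit by flipping the event indicator, so "events" are censorings.  Used
    for IPCW weights; right-continuous, with an explicit left-limit lookup.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        kmf = KaplanMeierFitter()
        kmf.fit(time, event_observed=1 - event)
        sf = kmf.survival_function_
        self._times = sf.index.to_numpy(dtype=float)
        self._surv = sf.iloc[:, 0].to_numpy(dtype=float)

    def at(self, t: np.ndarray) -> np.ndarray:
        """G(t), right-continuous."""
        idx = np.searchsorted(self._times, np.asarray(t, dtype=float), side="right") - 1
        return np.where(idx >= 0, self._surv[np.clip(idx, 0, None)], 1.0)

    def before(self, t: np.ndarray) -> np.ndarray:
        """Left limit G(t-)."""
        idx = np.searchsorted(self._times, np.asarray(t, dtype=float), side="left") - 1
        return np.where(idx >= 0, self._surv[np.clip(idx, 0, None)], 1.0)


def _pair_masks(theta: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Comparable-pair indicator and concordance score for ordered pairs.

    Pair (i, j) is comparable when ``t_i < t_j`` and patient i had the
    event; pairs whose earlier member is censored, and tied-time pairs, are
    not comparable.  Score: 1 if the earlier-event patient has the higher
    prognostic index, 0.5 on a tie in the index.
    """
    theta = np.asarray(theta, dtype=float).ravel()
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event).ravel()
    comparable = (time[:, None] < time[None, :]) & (event[:, None] == 1)
    d = theta[:, None] - theta[None, :]
    score = np.where(d > 0, 1.0, np.where(d == 0, 0.5, 0.0))
    return comparable, score


def c_harrell(theta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell's concordance index (ties in the index count 0.5)."""
    comparable, score = _pair_masks(theta, time, event)
    n_pairs = comparable.sum()
    if n_pairs == 0:
        raise ValueError("no comparable pairs: concordance undefined")
    return float(score[comparable].sum() / n_pairs)


def c_ipcw(
    theta: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    censoring: CensoringDistribution | None = None,
) -> float:
    """Concordance with inverse-probability-of-censoring pair weights.

    Each comparable pair is weighted ``1 / G(t_i-)^2`` where ``t_i`` is the
    earlier (event) time and ``G`` the Kaplan-Meier censoring survival —
    estimated from the given data unless a (training-set) estimate is
    supplied.  With no censoring, all weights are 1 and the value equals
    Harrell's C exactly.
    """
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event).ravel()
    if censoring is None:
        censoring = CensoringDistribution(time, event)
    comparable, score = _pair_masks(theta, time, event)
    g = censoring.before(time)
    usable = g > 0
    if not np.all(usable):
        warnings.warn("pairs with zero censoring-survival weight excluded from IPCW C")
    w = np.zeros_like(g)
    w[usable] = 1.0 / g[usable] ** 2
    W = comparable * w[:, None]
    total = W.sum()
    if total == 0:
        raise ValueError("no weighted comparable pairs: IPCW concordance undefined")
    return float((W * score).sum() / total)


@dataclass
class LogrankResult:
    statistic: float
    p_value: float


def logrank_dichotomized(theta: np.ndarray, time: np.ndarray, event: np.ndarray) -> LogrankResult:
    """Two-sample log-rank test after a median split of the prognostic index.

    Patients with an index strictly above the median form the high-risk
    group; patients exactly at the median go to the low-risk group.
    """
    theta = np.asarray(theta, dtype=float).ravel()
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event).ravel()
    cut = np.median(theta)
    high = theta > cut
    if high.all() or not high.any():
        raise ValueError("median split produced an empty risk group")
    res = logrank_test(time[high], time[~high], event[high], event[~high])
    return LogrankResult(statistic=float(res.test_statistic), p_value=float(res.p_value))


def integrated_brier(
    theta: np.ndarray,
    baseline: BaselineHazard,
    time: np.ndarray,
    event: np.ndarray,
    censoring: CensoringDistribution | None = None,
) -> float:
    """IPCW Brier score integrated over [0, t_max] and divided by t_max.

    Predicted survival comes from the (training-set) Breslow baseline:
    ``S_i(t) = exp(-H0(t) exp(theta_i))``.  At each grid time t,

        BS(t) = mean_i [ S_i(t)^2 1{t_i <= t, event} / G(t_i-)
                        + (1 - S_i(t))^2 1{t_i > t} / G(t) ]

    integrated by the trapezoid rule on the grid {0} + event times + t_max.
    """
    theta = np.asarray(theta, dtype=float).ravel()
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event).ravel()
    t_max = time.max()
    if t_max <= 0:
        raise ValueError("empty integration grid: no positive observation times")
    if censoring is None:
        censoring = CensoringDistribution(time, event)
    grid = np.unique(np.concatenate([[0.0], np.unique(time[event == 1]), [t_max]]))
    grid = grid[grid <= t_max]

    S = baseline.survival(theta, grid)  # n x |grid|
    g_before = censoring.before(time)
    w_event = np.where(g_before > 0, 1.0 / np.where(g_before > 0, g_before, 1.0), 0.0)
    g_grid = censoring.at(grid)
    with np.errstate(divide="ignore"):
        w_alive = np.where(g_grid > 0, 1.0 / np.where(g_grid > 0, g_grid, 1.0), 0.0)

    died = ((time[:, None] <= grid[None, :]) & (event[:, None] == 1)).astype(float)
    alive = (time[:, None] > grid[None, :]).astype(float)
    contrib = S**2 * died * w_event[:, None] + (1.0 - S) ** 2 * alive * w_alive[None, :]
    bs = contrib.mean(axis=0)
    return float(np.trapezoid(bs, grid) / t_max)


def evaluate_model(
    model: SurvivalNet, train_ds: SurvivalDataset, test_ds: SurvivalDataset
) -> EvaluationReport:
    """All four metrics of a fitted model on a held-out set.

    The Breslow baseline and the censoring Kaplan-Meier (for IPCW weights)
    are estimated on the training set, never on the test set.
    """
    theta_train = model.predict(train_ds.X)
    baseline = breslow_baseline(theta_train, train_ds.time, train_ds.event)
    censoring = CensoringDistribution(train_ds.time, train_ds.event)
    theta = model.predict(test_ds.X)
    return EvaluationReport(
        c_harrell=c_harrell(theta, test_ds.time, test_ds.event),
        c_ipcw=c_ipcw(theta, test_ds.time, test_ds.event, censoring=censoring),
        logrank_p=logrank_dichotomized(theta, test_ds.time, test_ds.event).p_value,
        integrated_brier=integrated_brier(
            theta, baseline, test_ds.time, test_ds.event, censoring=censoring
        ),
        n_test=test_ds.n_patients,
        n_events_test=test_ds.n_events,
    )


def repeated_holdout(
    ds: SurvivalDataset,
    spec: ModelSpec,
    cfg: TrainConfig | None = None,
    grid: list[dict] | None = None,
    n_repeats: int = 10,
    test_fraction: float = 0.2,
    k: int = 5,
    seed: int = 0,
) -> list[EvaluationReport]:
    """Repeated 80/20 evaluation: split, CV-select hyperparameters on the
    training part, refit on the full training part, score the held-out part.

    Per-repeat seeds are derived deterministically from the master seed.
    """
    from .model_selection import cv_search

    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(seed)
    repeat_seeds = rng.integers(0, 2**31 - 1, size=(n_repeats, 2))
    reports = []
    for r in range(n_repeats):
        split_seed, fit_seed = (int(s) for s in repeat_seeds[r])
        tr, te = train_test_split(ds, test_fraction, seed=split_seed)
        run_cfg = dataclasses.replace(cfg, seed=fit_seed)
        if grid and len(grid) > 1:
            profile = cv_search(tr, grid, k=k, cfg=run_cfg, base_spec=spec)
            best_spec = profile.best_spec
        elif grid:
            best_spec = dataclasses.replace(spec, **grid[0])
        else:
            best_spec = spec
        fit = train(tr, best_spec, run_cfg)
        reports.append(evaluate_model(fit.model, tr, te))
    return reports


def reports_to_frame(reports: list[EvaluationReport]) -> pd.DataFrame:
    """One row per repeat, one column per metric."""
    return pd.DataFrame([dataclasses.asdict(r) for r in reports])
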