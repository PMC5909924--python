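"""Censored survival data with expression features.

The universal input object is :class:`SurvivalDataset`: a patient x gene
matrix of (already normalized, log-transformed) expression values together
with an observed time and an event indicator per patient.  The risk-set
indicator matrix built here is what turns the Cox partial likelihood into a
single matrix product downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalDataset",
    "RiskSetMatrix",
    "SurvivalDataError",
    "SurvivalFormatError",
    "load_dataset",
    "save_dataset",
    "build_risk_matrix",
    "train_test_split",
]


class SurvivalDataError(ValueError):
    """Invalid survival data content (values, alignment, degenerate inputs)."""


class SurvivalFormatError(ValueError):
    """Malformed input file (missing columns, unparseable cells)."""


@dataclass
class SurvivalDataset:
    """Expression matrix plus right-censored survival outcome.

    Parameters
    ----------
    X
        ``(n, J)`` float matrix of log-expression values, patients in rows.
    time
        Observed time per patient (event or censoring), non-negative.
    event
        Indicator per patient: 1 = event (death) observed, 0 = censored.
    feature_names
        ``J`` unique gene/feature labels, column order of ``X``.
    patient_ids
        ``n`` patient labels, row order of ``X``.
    """

    X: np.ndarray
    time: np.ndarray
    event: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    patient_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n, j = self.X.shape
        if not self.feature_names:
            self.feature_names = [f"g{k}" for k in range(j)]
        if not self.patient_ids:
            self.patient_ids = [f"p{k}" for k in range(n)]
        if n < 2:
            raise SurvivalDataError(f"need at least 2 patients, got {n}")
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise SurvivalDataError("time/event length does not match X rows")
        if len(self.feature_names) != j:
            raise SurvivalDataError("feature_names length does not match X columns")
        if len(set(self.feature_names)) != j:
            raise SurvivalDataError("feature_names must be unique")
        if not np.all(np.isfinite(self.X)):
            raise SurvivalDataError("X contains missing or non-finite values")
        if not np.all(np.isfinite(self.time)) or np.any(self.time < 0):
            raise SurvivalDataError("time must be finite and >= 0")
        bad = ~np.isin(self.event, (0, 1))
        if np.any(bad):
            row = int(np.flatnonzero(bad)[0])
            raise SurvivalDataError(
                f"event must be 0 or 1; offending value {self.event[row]} "
                f"at row {row} (patient {self.patient_ids[row]})"
            )
        # An observed event at t=0 would put the patient at risk for no time
        # at all; censoring at 0 (lost immediately) is allowed.
        zero_event = (self.time == 0) & (self.event == 1)
        if np.any(zero_event):
            row = int(np.flatnonzero(zero_event)[0])
            raise SurvivalDataError(f"event at time 0 for patient {self.patient_ids[row]}")

    @property
    def n_patients(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx: np.ndarray) -> "SurvivalDataset":
        """Row subset in the given index order."""
        idx = np.asarray(idx, dtype=int)
        return SurvivalDataset(
            X=self.X[idx],
            time=self.time[idx],
            event=self.event[idx],
            feature_names=list(self.feature_names),
            patient_ids=[self.patient_ids[i] for i in idx],
        )


@dataclass
class RiskSetMatrix:
    """Binary risk-set indicator: ``R[i, j] = 1`` iff ``time[j] >= time[i]``.

    Row ``i`` marks the patients still at risk at patient ``i``'s observed
    time (ties included, so every diagonal entry is 1).  Tied event times
    share one denominator — the Breslow convention.
    """

    R: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R)
        n, m = self.R.shape
        if n != m:
            raise SurvivalDataError("risk-set matrix must be square")


def build_risk_matrix(time: np.ndarray) -> RiskSetMatrix:
    """Risk-set indicator matrix from the observed-time vector.

    ``R[i, j] == 1`` exactly when patient ``j`` is at risk at patient ``i``'s
    time, i.e. ``time[j] >= time[i]``.
    """
    time = np.asarray(time, dtype=float)
    if time.ndim != 1:
        raise SurvivalDataError("time must be a 1-d vector")
    if not np.all(np.isfinite(time)) or np.any(time < 0):
        raise SurvivalDataError("time must be finite and >= 0")
    R = (time[None, :] >= time[:, None]).astype(np.int8)
    return RiskSetMatrix(R=R)


def _detect_sep(path: str) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def load_dataset(expression_path: str, survival_path: str) -> SurvivalDataset:
    """Read expression + survival tables and align them on patient id.

    The expression file is a delimited matrix (header = feature names, first
    column = patient id); the survival file needs columns ``patient_id``,
    ``time`` and ``event``.  Patients missing from either file are dropped
    with a warning; row order follows the expression file.
    """
    expr = pd.read_csv(
        expression_path, sep=_detect_sep(expression_path), index_col=0,
        float_precision="round_trip",
    )
    expr.index = expr.index.astype(str)
    surv = pd.read_csv(
        survival_path, sep=_detect_sep(survival_path), dtype={0: str},
        float_precision="round_trip",
    )
    for col in ("patient_id", "time", "event"):
        if col not in surv.columns:
            raise SurvivalFormatError(
                f"survival file {survival_path!r} is missing required column {col!r}"
            )
    surv = surv.set_index(surv["patient_id"].astype(str))

    for col in expr.columns:
        coerced = pd.to_numeric(expr[col], errors="coerce")
        bad = coerced.isna() & expr[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise SurvivalFormatError(
                f"non-numeric value {expr.loc[row, col]!r} at row {row!r}, column {col!r} "
                f"of {expression_path!r}"
            )
        expr[col] = coerced
    if expr.isna().any().any():
        raise SurvivalDataError(f"missing expression values in {expression_path!r}")
    for col in ("time", "event"):
        coerced = pd.to_numeric(surv[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            row = bad.idxmax()
            raise SurvivalFormatError(
                f"non-numeric value in column {col!r} at patient {row!r} of {survival_path!r}"
            )
        surv[col] = coerced
    bad_event = ~surv["event"].isin((0, 1))
    if bad_event.any():
        row = bad_event.idxmax()
        raise SurvivalDataError(
            f"column 'event' must be 0/1; offending value {surv.loc[row, 'event']} "
            f"for patient {row!r}"
        )

    shared = [pid for pid in expr.index if pid in surv.index]
    if not shared:
        raise SurvivalDataError("no patients shared between expression and survival files")
    dropped = (set(expr.index) | set(surv.index)) - set(shared)
    if dropped:
        logger.warning(
            "dropping %d patient(s) absent from one of the files: %s",
            len(dropped), sorted(dropped)[:10],
        )
    expr = expr.loc[shared]
    surv = surv.loc[shared]
    return SurvivalDataset(
        X=expr.to_numpy(dtype=float),
        time=surv["time"].to_numpy(dtype=float),
        event=surv["event"].to_numpy(dtype=int),
        feature_names=[str(c) for c in expr.columns],
        patient_ids=list(expr.index),
    )


def save_dataset(ds: SurvivalDataset, expression_path: str, survival_path: str, sep: str = "\t") -> None:
    """Write the dataset in the same two-file layout :func:`load_dataset` reads."""
    pd.DataFrame(ds.X, index=ds.patient_ids, columns=ds.feature_names).to_csv(
        expression_path, sep=sep, index_label="patient_id"
    )
    pd.DataFrame(
        {"patient_id": ds.patient_ids, "time": ds.time, "event": ds.event}
    ).to_csv(survival_path, sep=sep, index=False)


def train_test_split(
    ds: SurvivalDataset,
    test_fraction: float,
    seed: int,
    max_retries: int = 100,
) -> tuple[SurvivalDataset, SurvivalDataset]:
    """Random disjoint train/test partition with at least one event per part.

    The training part gets ``ceil(n * (1 - test_fraction))`` patients.  If a
    draw leaves either part event-free, the split is redrawn up to
    ``max_retries`` times before giving up.
    """
    if not 0.0 < test_fraction < 1.0:
        raise SurvivalDataError("test_fraction must be in (0, 1)")
    n = ds.n_patients
    n_train = math.ceil(n * (1.0 - test_fraction))
    if not 0 < n_train < n:
        raise SurvivalDataError(f"degenerate split sizes for n={n}, f={test_fraction}")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
        test_idx = np.sort(perm[n_train:])
        if ds.event[train_idx].sum() >= 1 and ds.event[test_idx].sum() >= 1:
            return ds.subset(train_idx), ds.subset(test_idx)
    raise SurvivalDataError(
        f"could not produce a split with >= 1 event in both parts after {max_retries} tries"
    )
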