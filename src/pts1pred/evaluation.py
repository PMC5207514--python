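"""Confusion counting, classification metrics and cross-validation.

Four metrics summarise a binary confusion matrix (TP, FP, TN, FN):

    Acc  = (TP+TN) / (TP+FP+TN+FN)
    Sens = TP / (TP+FN)
    Spec = TN / (FP+TN)
    MCC  = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC is undefined (reported N.A.) when any marginal is zero. Cross-validation
is stratified k-fold with the bi-profile and the SVM refit inside each
training fold — profiles estimated on all data would leak held-out windows
into the features. Fold confusions are pooled before computing the headline
metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .seq_io import ProteinRecord, Window, windows_from_records

#: Decision cut-off grid used in published sweep tables.
DEFAULT_CUTOFFS: tuple[float, ...] = (-1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5)

#: Window lengths used for the input-length sweep.
DEFAULT_LENGTHS: tuple[int, ...] = (3, 5, 10, 15, 20, 25, 30, 35, 40)


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round half away from zero (the convention of the published tables)."""
    scale = 10**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError(f"negative confusion count: {self}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricsReport:
    """Acc/Sens/Spec/MCC; undefined values are NaN with explicit flags."""

    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float
    mcc_defined: bool
    confusion: ConfusionCounts

    def format_value(self, name: str, ndigits: int = 3) -> str:
        v = getattr(self, name)
        if name == "mcc" and not self.mcc_defined:
            return "N.A."
        if isinstance(v, float) and math.isnan(v):
            return "N.A."
        return f"{round_half_away(v, ndigits):.{ndigits}f}"


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """The four metrics from integer confusion counts.

    A zero Sens/Spec denominator yields NaN; an MCC denominator with any zero
    factor sets ``mcc_defined=False`` (matching the N.A. convention of
    published cut-off tables) rather than raising.
    """
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    acc = (c.tp + c.tn) / c.total
    sens = c.tp / c.n_pos if c.n_pos > 0 else float("nan")
    spec = c.tn / c.n_neg if c.n_neg > 0 else float("nan")
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom > 0:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
        defined = True
    else:
        mcc, defined = float("nan"), False
    return MetricsReport(acc, sens, spec, mcc, defined, c)


def reconstruct_confusion(
    sens: float, spec: float, n_pos: int, n_neg: int
) -> ConfusionCounts:
    """Recover integer confusion counts from printed sensitivity/specificity.

    TP = round(sens·P) and TN = round(spec·N), rounding half away from zero —
    the inverse of how rate tables are printed from integer counts. Lets a
    published sweep table be checked for internal consistency.
    """
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("sensitivity/specificity must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class sizes must be positive")
    tp = int(math.floor(sens * n_pos + 0.5))
    tn = int(math.floor(spec * n_neg + 0.5))
    return ConfusionCounts(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)


def confusion_from_scores(
    scores: Sequence[float], labels: Sequence[int], cutoff: float
) -> ConfusionCounts:
    """Count the confusion of thresholded scores: call positive iff score >= cutoff."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels are not aligned")
    calls = np.where(s >= cutoff, 1, -1)
    return ConfusionCounts(
        tp=int(np.sum((calls == 1) & (y == 1))),
        fp=int(np.sum((calls == 1) & (y == -1))),
        tn=int(np.sum((calls == -1) & (y == -1))),
        fn=int(np.sum((calls == -1) & (y == 1))),
    )


@dataclass(frozen=True)
class CVResult:
    """Pooled-confusion headline report plus per-fold reports and raw scores."""

    pooled: MetricsReport
    folds: tuple[MetricsReport, ...]
    scores: np.ndarray
    labels: np.ndarray

    def sweep(self, cutoffs: Sequence[float] = DEFAULT_CUTOFFS) -> pd.DataFrame:
        return cutoff_sweep(self.scores, self.labels, cutoffs)


def cross_validate(
    pos_windows: Sequence[Window],
    neg_windows: Sequence[Window],
    k: int = 5,
    cutoff: float = 1.0,
    kernel: str = "rbf",
    C: float = 1.0,
    gamma: float | str = "scale",
    alpha: float = 1.0,
    seed: int = 0,
    uniform_priors: bool = False,
) -> CVResult:
    """Stratified k-fold CV of the bi-profile + SVM pipeline.

    Folds are drawn at random from ``seed`` with class stratification (random
    unstratified subsampling can produce single-class folds at typical
    training-set sizes). Within each fold both the profile pair and the SVM
    are fit on the training windows only; held-out windows are scored, all
    held-out scores are pooled, and the pooled confusion at ``cutoff`` gives
    the headline report.
    """
    from .classifier import train as _train, decision_scores as _scores

    n1, n0 = len(pos_windows), len(neg_windows)
    if k < 2:
        raise ValueError("k must be >= 2")
    if min(n1, n0) < k:
        raise ValueError(f"k={k} exceeds smallest class size {min(n1, n0)}")
    windows = list(pos_windows) + list(neg_windows)
    y = np.array([+1] * n1 + [-1] * n0)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = np.empty(len(windows))
    fold_reports = []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        tr_pos = [windows[i] for i in train_idx if y[i] == 1]
        tr_neg = [windows[i] for i in train_idx if y[i] == -1]
        model = _train(
            tr_pos, tr_neg, kernel=kernel, C=C, gamma=gamma, alpha=alpha,
            seed=seed, uniform_priors=uniform_priors,
        )
        held = [windows[i] for i in test_idx]
        scores[test_idx] = _scores(model, held)
        fold_reports.append(
            compute_metrics(confusion_from_scores(scores[test_idx], y[test_idx], cutoff))
        )
    pooled = compute_metrics(confusion_from_scores(scores, y, cutoff))
    return CVResult(pooled, tuple(fold_reports), scores, y)


def cutoff_sweep(
    scores: Sequence[float],
    labels: Sequence[int],
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> pd.DataFrame:
    """Metrics at each decision cut-off; one row per cut-off.

    Columns: cutoff, tp, fp, tn, fn, sensitivity, specificity, accuracy, mcc
    (NaN where undefined).
    """
    if len(cutoffs) == 0:
        raise ValueError("empty cutoff list")
    rows = []
    for c in cutoffs:
        rep = compute_metrics(confusion_from_scores(scores, labels, c))
        rows.append(
            {
                "cutoff": c,
                "tp": rep.confusion.tp,
                "fp": rep.confusion.fp,
                "tn": rep.confusion.tn,
                "fn": rep.confusion.fn,
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "accuracy": rep.accuracy,
                "mcc": rep.mcc,
            }
        )
    return pd.DataFrame(rows)


def format_sweep_table(sweep: pd.DataFrame, ndigits: int = 3) -> str:
    """Render a cut-off sweep in the published layout: cut-offs as columns,
    Sensitivity/Specificity/Accuracy/MCC as rows, N.A. for undefined MCC."""
    def fmt(v: float) -> str:
        return "N.A." if (isinstance(v, float) and math.isnan(v)) else (
            f"{round_half_away(v, ndigits):.{ndigits}f}"
        )

    header = "Cut-off Value\t" + "\t".join(f"{c:g}" for c in sweep["cutoff"])
    lines = [header]
    for name, col in [
        ("Sensitivity", "sensitivity"),
        ("Specificity", "specificity"),
        ("Accuracy", "accuracy"),
        ("MCC", "mcc"),
    ]:
        lines.append(name + "\t" + "\t".join(fmt(v) for v in sweep[col]))
    return "\n".join(lines) + "\n"


def length_sweep(
    pos_records: Sequence[ProteinRecord],
    neg_records: Sequence[ProteinRecord],
    lengths: Sequence[int] = DEFAULT_LENGTHS,
    k: int = 5,
    cutoff: float = 1.0,
    kernel: str = "rbf",
    C: float = 1.0,
    gamma: float | str = "scale",
    alpha: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the full CV pipeline at each C-terminal window length.

    Measures how much signal the residues upstream of the PTS1 tripeptide
    contribute: L=3 sees only the motif, longer windows add adjacent-sequence
    positions. One row per length with pooled CV metrics.
    """
    if any(L < 1 for L in lengths):
        raise ValueError("window lengths must be >= 1")
    rows = []
    for L in lengths:
        cv = cross_validate(
            windows_from_records(pos_records, L),
            windows_from_records(neg_records, L),
            k=k, cutoff=cutoff, kernel=kernel, C=C, gamma=gamma,
            alpha=alpha, seed=seed,
        )
        rep = cv.pooled
        rows.append(
            {
                "length": L,
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "accuracy": rep.accuracy,
                "mcc": rep.mcc,
            }
        )
    return pd.DataFrame(rows)
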