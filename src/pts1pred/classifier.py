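"""Soft-margin SVM on bi-profile Bayes features.

The trained artefact is self-contained: it embeds the profile pair and the
window length it was trained with, so a saved model can score any FASTA
without access to the training data. Decision values are the raw
(uncalibrated) SVM outputs — typically within about −3…3 for these models —
and classification happens by comparing them with a user-chosen cut-off
(default 1.0; 1.5 is the conservative choice for whole-proteome scans).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .bpb import ProfilePair, build_profile_pair, encode_many
from .seq_io import ProteinRecord, Window, windows_from_records

MODEL_MAGIC = "pts1pred-model"
MODEL_FORMAT_VERSION = 1

#: Hyperparameter grids for the default grid search (powers of two, the
#: customary libsvm-style search space).
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-15, 4, 2))

#: Default decision cut-off; whole-proteome scans use SCAN_CUTOFF.
DEFAULT_CUTOFF = 1.0
SCAN_CUTOFF = 1.5


class ModelFormatError(RuntimeError):
    """Raised when a model file is corrupt or of an unsupported version."""


def data_fingerprint(
    pos: Sequence[Window] | Sequence[ProteinRecord],
    neg: Sequence[Window] | Sequence[ProteinRecord],
) -> str:
    """Order-insensitive digest of a labelled dataset's residue content."""
    h = hashlib.sha256()
    for tag, items in (("+", pos), ("-", neg)):
        for r in sorted(x.residues for x in items):
            h.update(tag.encode())
            h.update(r.encode())
    return h.hexdigest()[:16]


@dataclass
class TrainedModel:
    """Fitted SVM plus everything needed to score raw sequences."""

    svm: SVC
    pair: ProfilePair
    length: int
    kernel: str
    C: float
    gamma: float | str
    alpha: float
    seed: int
    n_pos: int
    n_neg: int
    train_fingerprint: str = ""

    @property
    def model_id(self) -> str:
        return (
            f"{self.kernel}-L{self.length}-C{self.C:g}-g{self.gamma}"
            f"-a{self.alpha:g}-s{self.seed}"
        )


def train(
    pos_windows: Sequence[Window],
    neg_windows: Sequence[Window],
    kernel: str = "rbf",
    C: float = 1.0,
    gamma: float | str = "scale",
    alpha: float = 1.0,
    seed: int = 0,
    class_weight: dict | str | None = None,
    uniform_priors: bool = False,
) -> TrainedModel:
    """Fit profiles and SVM on labelled training windows.

    Profiles are built from the given windows only (callers doing
    cross-validation must pass training folds, never the full data). The SVM
    sees BPB vectors with labels +1/−1. ``class_weight`` is exposed for the
    1:2 positive:negative imbalance typical of curated sets but defaults to
    none. Training is deterministic for fixed inputs and seed.
    """
    if not pos_windows or not neg_windows:
        raise ValueError("both classes must be non-empty")
    if C <= 0:
        raise ValueError(f"C must be > 0, got {C}")
    if isinstance(gamma, (int, float)) and gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    pair = build_profile_pair(
        pos_windows, neg_windows, alpha=alpha, uniform_priors=uniform_priors
    )
    X = np.vstack(
        [encode_many(pos_windows, pair), encode_many(neg_windows, pair)]
    )
    y = np.array([+1] * len(pos_windows) + [-1] * len(neg_windows))
    svm = SVC(
        kernel=kernel, C=C, gamma=gamma, class_weight=class_weight,
        random_state=seed, cache_size=200,
    )
    svm.fit(X, y)
    return TrainedModel(
        svm=svm, pair=pair, length=pair.length, kernel=kernel, C=C,
        gamma=gamma, alpha=alpha, seed=seed,
        n_pos=len(pos_windows), n_neg=len(neg_windows),
        train_fingerprint=data_fingerprint(pos_windows, neg_windows),
    )


def decision_scores(model: TrainedModel, windows: Sequence[Window]) -> np.ndarray:
    """Raw SVM decision values for a batch of windows (no clipping)."""
    if not windows:
        raise ValueError("empty window list")
    if any(len(w) != model.length for w in windows):
        raise ValueError(f"window length != model length {model.length}")
    X = encode_many(windows, model.pair)
    scores = model.svm.decision_function(X)
    # sklearn orients the decision axis by label sort order; classes_ is
    # [-1, +1] so positive scores already mean the positive class.
    return scores


def decision_score(model: TrainedModel, window: Window) -> float:
    return float(decision_scores(model, [window])[0])


@dataclass(frozen=True)
class PredictionResult:
    id: str
    score: float
    label: int
    cutoff: float


def predict(
    model: TrainedModel,
    records: Sequence[ProteinRecord],
    cutoff: float = DEFAULT_CUTOFF,
) -> list[PredictionResult]:
    """Score full-length records: extract each C-terminal window per the
    model's length (short proteins padded), call positive iff score >= cutoff."""
    if not records:
        raise ValueError("empty record list")
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    windows = windows_from_records(records, model.length)
    scores = decision_scores(model, windows)
    return [
        PredictionResult(r.id, float(s), +1 if s >= cutoff else -1, cutoff)
        for r, s in zip(records, scores)
    ]


def predictions_to_frame(results: Sequence[PredictionResult], model_id: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in results],
            "score": [f"{r.score:.3f}" for r in results],
            "label": [r.label for r in results],
            "cutoff": [f"{r.cutoff:g}" for r in results],
            "model": model_id,
        }
    )


def grid_search(
    pos_windows: Sequence[Window],
    neg_windows: Sequence[Window],
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    k: int = 5,
    seed: int = 0,
    kernel: str = "rbf",
    alpha: float = 1.0,
    cutoff: float = 0.0,
) -> tuple[float, float, pd.DataFrame]:
    """Select (C, gamma) by stratified k-fold CV pooled accuracy.

    Profiles are rebuilt inside every training fold for every cell. Ties are
    broken toward smaller C, then smaller gamma (prefer the smoother model).
    Returns the winning pair and the full CV table.
    """
    from .evaluation import cross_validate

    if not C_grid or not gamma_grid:
        raise ValueError("empty hyperparameter grid")
    rows = []
    best = None
    for C in C_grid:
        for g in gamma_grid:
            cv = cross_validate(
                pos_windows, neg_windows, k=k, cutoff=cutoff, kernel=kernel,
                C=C, gamma=g, alpha=alpha, seed=seed,
            )
            acc = cv.pooled.accuracy
            rows.append({"C": C, "gamma": g, "accuracy": acc})
            key = (-acc, C, g)
            if best is None or key < best[0]:
                best = (key, C, g)
    assert best is not None
    return best[1], best[2], pd.DataFrame(rows)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialise a model; the on-disk dict is magic- and version-tagged."""
    payload = {
        "magic": MODEL_MAGIC,
        "format_version": MODEL_FORMAT_VERSION,
        "model": model,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupt pickle stream
        raise ModelFormatError(f"{path}: not a readable model file ({exc})") from exc
    if not isinstance(payload, dict) or payload.get("magic") != MODEL_MAGIC:
        raise ModelFormatError(f"{path}: missing model magic")
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: unsupported model format version "
            f"{payload.get('format_version')!r}"
        )
    return payload["model"]
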