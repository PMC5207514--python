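"""Bi-profile Bayes (BPB) encoding and the naive-Bayes log-odds baseline.

A *position profile* is a positions × residues matrix of class-conditional
probabilities P(a | position i, class c), estimated from training windows by
position-specific counting with a Laplace pseudocount. The *bi-profile* pairs
the positive-class and negative-class profiles; a window is encoded as the
length-2L vector of its own residues' probabilities under the positive
profile followed by the negative profile. The same pair of profiles also
yields a naive-Bayes classifier: under position independence,
P(S|c) = ∏_i P(s_i|c), and the decision is the sign of
log P(c+|S) − log P(c−|S).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .seq_io import ALPHABET, AA_INDEX, Window

N_SYMBOLS = len(ALPHABET)  # 21


@dataclass(frozen=True)
class PositionProfile:
    """Class-conditional per-position residue probabilities.

    ``probs[i, a]`` is P(symbol a | position i, this class); rows follow the
    window position order ``-(L-1) … 0`` and each row sums to 1. ``counts``
    keeps the raw per-position symbol counts the probabilities were estimated
    from, ``n_windows`` the number of training windows (the paper-style m_i is
    the same at every position since windows are fixed-length).
    """

    probs: np.ndarray
    alpha: float
    label: int
    n_windows: int

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def positions(self) -> list[int]:
        L = self.length
        return list(range(-(L - 1), 1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.probs, index=self.positions, columns=list(ALPHABET)
        ).rename_axis("position")

    def to_tsv(self, path: str | Path) -> None:
        """Export as TSV (positions as rows, residues as columns) for logo tools."""
        self.to_frame().to_csv(path, sep="\t", float_format="%.6f")


@dataclass(frozen=True)
class ProfilePair:
    """Positive and negative position profiles plus class priors."""

    positive: PositionProfile
    negative: PositionProfile
    priors: tuple[float, float]

    def __post_init__(self) -> None:
        if self.positive.length != self.negative.length:
            raise ValueError("profile lengths differ")
        p1, p0 = self.priors
        if not (0.0 < p1 < 1.0 and 0.0 < p0 < 1.0) or abs(p1 + p0 - 1.0) > 1e-9:
            raise ValueError(f"priors must be in (0,1) and sum to 1, got {self.priors}")

    @property
    def length(self) -> int:
        return self.positive.length


def _window_indices(windows: Sequence[Window]) -> np.ndarray:
    lengths = {len(w) for w in windows}
    if len(lengths) != 1:
        raise ValueError(f"windows have mixed lengths {sorted(lengths)}")
    return np.array(
        [[AA_INDEX[c] for c in w.residues] for w in windows], dtype=np.intp
    )


def build_position_profile(
    windows: Sequence[Window], alpha: float = 1.0, label: int = +1
) -> PositionProfile:
    """Estimate P(a | position, class) by counting with pseudocount ``alpha``.

    entry(i, a) = (count of a at position i + alpha) / (m + 21·alpha)
    where m is the number of windows. ``alpha=0`` gives raw relative
    frequencies (zero entries possible); ``alpha>0`` guarantees strictly
    positive entries.
    """
    if not windows:
        raise ValueError("empty window list")
    if alpha < 0:
        raise ValueError(f"pseudocount must be >= 0, got {alpha}")
    idx = _window_indices(windows)
    m, L = idx.shape
    counts = np.zeros((L, N_SYMBOLS), dtype=np.int64)
    for i in range(L):
        np.add.at(counts[i], idx[:, i], 1)
    probs = (counts + alpha) / (m + N_SYMBOLS * alpha)
    return PositionProfile(probs=probs, alpha=alpha, label=label, n_windows=m)


def build_profile_pair(
    pos_windows: Sequence[Window],
    neg_windows: Sequence[Window],
    alpha: float = 1.0,
    uniform_priors: bool = False,
) -> ProfilePair:
    """Build the bi-profile from labelled training windows.

    Priors default to empirical class frequencies; ``uniform_priors`` forces
    (0.5, 0.5), useful when the class ratio is a sampling artefact rather
    than a population property.
    """
    if not pos_windows or not neg_windows:
        raise ValueError("both classes must be non-empty")
    pos = build_position_profile(pos_windows, alpha, label=+1)
    neg = build_position_profile(neg_windows, alpha, label=-1)
    if pos.length != neg.length:
        raise ValueError("positive and negative windows have different lengths")
    if uniform_priors:
        priors = (0.5, 0.5)
    else:
        n1, n0 = len(pos_windows), len(neg_windows)
        priors = (n1 / (n1 + n0), n0 / (n1 + n0))
    return ProfilePair(positive=pos, negative=neg, priors=priors)


def encode_bpb(window: Window, pair: ProfilePair) -> np.ndarray:
    """Encode a window as its BPB feature vector of length 2L.

    Entries 1…L are P(s_i | positive class) at each position (read in position
    order −(L−1)…0), entries L+1…2L the same probabilities under the negative
    profile.
    """
    if len(window) != pair.length:
        raise ValueError(
            f"window length {len(window)} != profile length {pair.length}"
        )
    idx = np.array([AA_INDEX[c] for c in window.residues], dtype=np.intp)
    rows = np.arange(pair.length)
    return np.concatenate(
        [pair.positive.probs[rows, idx], pair.negative.probs[rows, idx]]
    )


def encode_many(windows: Sequence[Window], pair: ProfilePair) -> np.ndarray:
    """Vectorised :func:`encode_bpb` over a window list → (n, 2L) matrix."""
    idx = _window_indices(windows)
    if idx.shape[1] != pair.length:
        raise ValueError("window length != profile length")
    rows = np.arange(pair.length)
    return np.hstack(
        [pair.positive.probs[rows, idx], pair.negative.probs[rows, idx]]
    )


def naive_bayes_score(
    window: Window, pair: ProfilePair, use_priors: bool = True
) -> float:
    """Naive-Bayes log-odds of the positive class for one window.

    Σ_i [log P(s_i|c+) − log P(s_i|c−)], plus log P(c+) − log P(c−) when
    ``use_priors``. Natural log; only the sign and relative ordering matter.
    Requires profiles built with alpha > 0 (zero probabilities are a hard
    error, not −inf).
    """
    v = encode_bpb(window, pair)
    L = pair.length
    if np.any(v <= 0.0):
        raise ValueError(
            "zero probability in profile; rebuild profiles with alpha > 0"
        )
    score = float(np.sum(np.log(v[:L])) - np.sum(np.log(v[L:])))
    if use_priors:
        score += float(np.log(pair.priors[0]) - np.log(pair.priors[1]))
    return score


def naive_bayes_classify(score: float) -> int:
    """Sign decision: +1 if the log-odds is positive, −1 otherwise.

    An exact tie (score == 0) is called negative — the conservative choice
    for a targeting-signal screen.
    """
    return +1 if score > 0 else -1
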