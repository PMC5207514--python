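"""Per-position amino-acid composition and positional contrast.

The composition matrix is the data behind a sequence logo: at every window
position, the relative frequency of each of the 20 standard residues among
observed (non-pad) symbols. Contrasting the positive-class and
negative-class matrices position by position quantifies where peroxisomal
C-termini deviate compositionally from non-peroxisomal ones — the PTS1
tripeptide positions −2…0 dominate, but upstream positions carry bias too.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .bpb import build_position_profile
from .seq_io import AMINO_ACIDS, Window


def position_composition(windows: Sequence[Window]) -> pd.DataFrame:
    """Relative residue frequencies per position, pads excluded.

    Rows are positions −(L−1)…0, columns the 20 standard residues; each row
    sums to 1 over the residues actually observed there. A position where
    every window is padding (possible when all sources are shorter than L)
    is flagged empty by an all-NaN row.

    The α=0 position profile restricted to the standard residues gives the
    same numbers up to the pad renormalisation.
    """
    profile = build_position_profile(windows, alpha=0.0)
    counts = profile.probs[:, : len(AMINO_ACIDS)] * profile.n_windows
    observed = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(observed > 0, counts / observed, np.nan)
    return pd.DataFrame(
        freqs, index=profile.positions, columns=list(AMINO_ACIDS)
    ).rename_axis("position")


def composition_contrast(pos: pd.DataFrame, neg: pd.DataFrame) -> pd.Series:
    """Per-position total variation distance ½·Σ_a |p(a) − q(a)|.

    Symmetric, bounded in [0, 1]; 0 for identical compositions, 1 for
    disjoint residue supports. NaN where either matrix has an empty
    (all-pad) row.
    """
    if pos.shape != neg.shape or list(pos.index) != list(neg.index):
        raise ValueError("composition matrices have different shapes or positions")
    tv = 0.5 * np.abs(pos.to_numpy() - neg.to_numpy()).sum(axis=1)
    return pd.Series(tv, index=pos.index, name="tv_distance")


def top_contrast_positions(
    contrast: pd.Series, n: int, exclude: Sequence[int] = ()
) -> list[int]:
    """Positions with the n largest divergences, optionally excluding some
    (e.g. the motif positions −2…0, which trivially dominate)."""
    kept = contrast.drop(index=list(exclude), errors="ignore").dropna()
    return list(kept.sort_values(ascending=False).index[:n])
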