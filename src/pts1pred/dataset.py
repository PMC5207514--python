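"""Labelled datasets: assembly, redundancy filtering and synthetic generation.

The synthetic generator emulates the statistical structure the predictor
assumes in curated two-class training sets: positives end in a PTS1-like
tripeptide and carry enriched residues at a handful of upstream positions;
negatives are drawn from the background composition with their terminal
tripeptide rejection-sampled out of the motif set, so any learned separation
is attributable to the modelled signal. Class sizes default to the 1:2
positive:negative ratio typical of curated sets (90 vs 176 for the
Arabidopsis-sized configuration).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .seq_io import AMINO_ACIDS, ProteinRecord, extract_cterminal_window

#: Canonical and common non-canonical PTS1 tripeptides used by the generator.
DEFAULT_MOTIFS: tuple[str, ...] = ("SKL", "ARL", "SRL", "SKM", "PKL", "SRM")

#: Upstream positions given enriched residues in synthetic positives,
#: mirroring where real peroxisomal C-termini show composition bias.
DEFAULT_BIASED_POSITIONS: dict[int, tuple[str, float]] = {
    -22: ("P", 0.5),
    -21: ("S", 0.5),
    -20: ("A", 0.5),
    -14: ("L", 0.5),
    -6: ("R", 0.5),
    -5: ("S", 0.5),
    -4: ("K", 0.5),
}

#: Approximate background amino-acid frequencies of plant proteomes
#: (order follows AMINO_ACIDS), for the natural-composition option.
NATURAL_AA_FREQS: dict[str, float] = {
    "A": 0.063, "C": 0.018, "D": 0.054, "E": 0.067, "F": 0.043,
    "G": 0.064, "H": 0.023, "I": 0.053, "K": 0.061, "L": 0.095,
    "M": 0.024, "N": 0.043, "P": 0.048, "Q": 0.035, "R": 0.054,
    "S": 0.090, "T": 0.051, "V": 0.068, "W": 0.012, "Y": 0.029,
}

_REJECTION_CAP = 1000


class GenerationError(RuntimeError):
    """Raised when negative rejection sampling cannot avoid the motif set."""


@dataclass(frozen=True)
class LabeledDataset:
    """Records with aligned +1/−1 labels."""

    records: tuple[ProteinRecord, ...]
    labels: tuple[int, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.records) != len(self.labels):
            raise ValueError("records and labels differ in length")
        if not (set(self.labels) == {+1, -1}):
            raise ValueError("both classes must be present")

    @property
    def positives(self) -> list[ProteinRecord]:
        return [r for r, y in zip(self.records, self.labels) if y == +1]

    @property
    def negatives(self) -> list[ProteinRecord]:
        return [r for r, y in zip(self.records, self.labels) if y == -1]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the two-class C-terminal sequence generator.

    ``biased_positions`` maps a C-terminal coordinate (0 = last residue) to
    (enriched residue, enrichment weight): with probability equal to the
    weight the position holds the enriched residue, otherwise a background
    draw. ``background`` is "uniform" (the default — keeps the null exactly
    known), "natural", or an explicit residue→frequency mapping.
    """

    n_pos: int = 90
    n_neg: int = 176
    length: int = 30
    motifs: tuple[str, ...] = DEFAULT_MOTIFS
    biased_positions: Mapping[int, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_BIASED_POSITIONS)
    )
    background: str | Mapping[str, float] = "uniform"
    min_length: int = 50
    max_length: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("class sizes must be >= 1")
        if not (1 <= self.min_length <= self.max_length):
            raise ValueError("invalid sequence length range")
        for m in self.motifs:
            if len(m) != 3 or set(m) - set(AMINO_ACIDS):
                raise ValueError(f"motif {m!r} is not a standard tripeptide")
        for p, (res, w) in self.biased_positions.items():
            if p > -3:
                raise ValueError(f"biased position {p} overlaps the motif (-2…0)")
            if res not in AMINO_ACIDS or not (0.0 < w <= 1.0):
                raise ValueError(f"bad enrichment at position {p}: {(res, w)}")

    def background_probs(self) -> np.ndarray:
        if isinstance(self.background, str):
            if self.background == "uniform":
                return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
            if self.background == "natural":
                freqs = NATURAL_AA_FREQS
            else:
                raise ValueError(f"unknown background {self.background!r}")
        else:
            freqs = dict(self.background)
        p = np.array([freqs[a] for a in AMINO_ACIDS], dtype=float)
        return p / p.sum()


def _draw_background(rng: np.random.Generator, n: int, p: np.ndarray) -> list[str]:
    return list(rng.choice(list(AMINO_ACIDS), size=n, p=p))


def generate_synthetic(spec: SyntheticSpec) -> LabeledDataset:
    """Generate a labelled synthetic dataset, deterministic per seed.

    Positives: background sequence, a motif drawn uniformly from the motif
    set at the last three positions, enriched residues at the biased
    positions with their stated weights. Negatives: pure background with the
    terminal tripeptide resampled (up to a fixed cap) until it falls outside
    the motif set.
    """
    rng = np.random.default_rng(spec.seed)
    bg = spec.background_probs()
    motif_set = set(spec.motifs)
    records: list[ProteinRecord] = []
    labels: list[int] = []

    for j in range(spec.n_pos):
        n = int(rng.integers(spec.min_length, spec.max_length + 1))
        seq = _draw_background(rng, n, bg)
        motif = spec.motifs[int(rng.integers(len(spec.motifs)))]
        seq[-3:] = list(motif)
        for pos, (res, w) in spec.biased_positions.items():
            i = n - 1 + pos
            if i >= 0 and rng.random() < w:
                seq[i] = res
        records.append(
            ProteinRecord(f"POS_{j + 1:04d}", "".join(seq), "synthetic positive")
        )
        labels.append(+1)

    for j in range(spec.n_neg):
        n = int(rng.integers(spec.min_length, spec.max_length + 1))
        seq = _draw_background(rng, n, bg)
        for _ in range(_REJECTION_CAP):
            if "".join(seq[-3:]) not in motif_set:
                break
            seq[-3:] = _draw_background(rng, 3, bg)
        else:
            raise GenerationError(
                "could not sample a terminal tripeptide outside the motif set; "
                "motif set too broad for the background"
            )
        records.append(
            ProteinRecord(f"NEG_{j + 1:04d}", "".join(seq), "synthetic negative")
        )
        labels.append(-1)

    return LabeledDataset(
        tuple(records), tuple(labels),
        provenance=f"synthetic(seed={spec.seed}, n_pos={spec.n_pos}, "
        f"n_neg={spec.n_neg})",
    )


def redundancy_filter(
    records: Sequence[ProteinRecord],
    identity_threshold: float = 0.9,
    window_length: int = 30,
) -> list[ProteinRecord]:
    """Greedy redundancy reduction on C-terminal window identity.

    Iterates records in input order and keeps one iff its fraction of
    matching window positions against every already-kept record is below the
    threshold. A deliberately simple, fully reproducible stand-in for
    cluster-based redundancy removal of curated sets; it is not equivalent
    to CD-Hit/BLAST clustering.
    """
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError(f"identity threshold must be in (0, 1], got {identity_threshold}")
    kept: list[ProteinRecord] = []
    kept_windows: list[str] = []
    for r in records:
        w = extract_cterminal_window(r, window_length).residues
        if all(
            sum(a == b for a, b in zip(w, kw)) / window_length < identity_threshold
            for kw in kept_windows
        ):
            kept.append(r)
            kept_windows.append(w)
    return kept


def assemble_dataset(
    pos_records: Sequence[ProteinRecord],
    neg_records: Sequence[ProteinRecord],
    provenance: str = "",
) -> LabeledDataset:
    """Concatenate positive and negative records with +1/−1 labels.

    Order is stable (positives first). Ids must be disjoint across classes.
    """
    if not pos_records or not neg_records:
        raise ValueError("both classes must be non-empty")
    collisions = {r.id for r in pos_records} & {r.id for r in neg_records}
    if collisions:
        raise ValueError(f"ids present in both classes: {sorted(collisions)[:5]}")
    records = tuple(pos_records) + tuple(neg_records)
    labels = (+1,) * len(pos_records) + (-1,) * len(neg_records)
    return LabeledDataset(records, labels, provenance=provenance)
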