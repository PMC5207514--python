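"""FASTA I/O, residue canonicalisation and C-terminal window extraction.

All downstream modules see protein sequences through two types defined here:
:class:`ProteinRecord` (a cleaned full-length sequence) and :class:`Window`
(the last ``L`` residues, positions labelled ``-(L-1) … 0`` with 0 at the
C-terminus, the convention used throughout for profiles and composition
matrices).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Full residue alphabet: standard amino acids plus 'X', which doubles as
#: "unknown residue" and as the left-padding symbol for short proteins.
ALPHABET: str = AMINO_ACIDS + "X"

AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}

_STANDARD_SET = frozenset(AMINO_ACIDS)


class SequenceError(ValueError):
    """Raised for sequences that cannot be canonicalised."""


def clean_sequence(raw: str) -> str:
    """Canonicalise a raw residue string.

    Uppercases, strips whitespace, removes a single trailing stop ``*``, and
    maps every non-standard symbol (B, Z, J, U, O, gaps, remaining stops, …)
    to ``'X'``.

    Raises
    ------
    SequenceError
        If the sequence is empty after cleaning.
    """
    s = "".join(raw.split()).upper()
    if s.endswith("*"):
        s = s[:-1]
    cleaned = "".join(c if c in _STANDARD_SET else "X" for c in s)
    if not cleaned:
        raise SequenceError("sequence empty after cleaning")
    return cleaned


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence: unique id, free-text description, cleaned residues."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"{self.id}: empty residue string")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise SequenceError(
                f"{self.id}: non-alphabet symbols {sorted(bad)}; "
                "run clean_sequence first"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Window:
    """Fixed-length C-terminal residue window.

    Position labels run ``-(L-1) … 0``; label 0 is always the last residue of
    the source protein. When the source is shorter than ``L`` the missing
    N-terminal cells hold ``'X'`` and occupy the most-negative positions.
    """

    residues: str
    source_id: str = ""

    def __post_init__(self) -> None:
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise SequenceError(f"window contains non-alphabet symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> list[int]:
        L = len(self.residues)
        return list(range(-(L - 1), 1))


def extract_cterminal_window(record: ProteinRecord, length: int = 30) -> Window:
    """Extract the last ``length`` residues, left-padding short proteins with 'X'."""
    if length < 1:
        raise ValueError(f"window length must be >= 1, got {length}")
    tail = record.residues[-length:]
    return Window("X" * (length - len(tail)) + tail, source_id=record.id)


def windows_from_records(
    records: Iterable[ProteinRecord], length: int = 30
) -> list[Window]:
    return [extract_cterminal_window(r, length) for r in records]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into cleaned :class:`ProteinRecord` objects.

    Entry order is preserved. Duplicate ids are warned about and
    suffix-deduplicated (``id``, ``id.2``, ``id.3`` …).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        seen[rid] = seen.get(rid, 0) + 1
        if seen[rid] > 1:
            new_id = f"{rid}.{seen[rid]}"
            warnings.warn(f"duplicate FASTA id {rid!r}; renamed to {new_id!r}")
            rid = new_id
        desc = entry.description[len(entry.id) :].strip()
        records.append(ProteinRecord(rid, clean_sequence(str(entry.seq)), desc))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Sequence[ProteinRecord], path: str | Path, width: int = 60
) -> None:
    """Write records as wrapped FASTA; round-trips ids and residues exactly."""
    path = Path(path)
    with path.open("w") as fh:
        for r in records:
            header = f">{r.id} {r.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(r.residues), width):
                fh.write(r.residues[i : i + width] + "\n")
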