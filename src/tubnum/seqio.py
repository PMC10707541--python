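"""Sequence and alignment I/O.

FASTA and Clustal parsing is delegated to Biopython; this module adds the
validation and normalisation rules used throughout the package:

* residues are uppercased and restricted to the 20 standard amino acids plus
  ``X`` (unknown); ambiguity codes ``B``/``Z``/``U``/``O`` are mapped to ``X``
  with a logged warning,
* gap characters ``-`` and ``.`` are both accepted and normalised to ``-``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = set(AMINO_ACIDS) | {"X"}
_AMBIGUOUS = {"B": "X", "Z": "X", "U": "X", "O": "X"}
GAP = "-"

FAMILIES = ("alpha", "beta", "gamma", "unassigned")

__all__ = [
    "AMINO_ACIDS",
    "ALPHABET",
    "GAP",
    "FAMILIES",
    "Sequence",
    "MSA",
    "ParseError",
    "normalize_residues",
    "read_fasta",
    "write_fasta",
    "read_msa",
    "write_msa",
]


class ParseError(ValueError):
    """Raised for malformed sequence/alignment input; carries file context."""


@dataclass(frozen=True)
class Sequence:
    """A protein sequence with an accession/name and optional family tag."""

    id: str
    residues: str
    family: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        if self.family not in FAMILIES:
            raise ValueError(f"{self.id}: unknown family {self.family!r}")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"{self.id}: illegal residue characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MSA:
    """A multiple sequence alignment: equal-length gapped rows.

    Row ids and de-gapped residues reproduce the input sequences.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]  # gapped, normalised residue strings
    family: str = "unassigned"

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an MSA needs at least 2 rows")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        n = len(self.rows[0])
        ragged = [i for i, r in zip(self.ids, self.rows) if len(r) != n]
        if ragged:
            raise ValueError(f"rows differ in aligned length: {ragged}")
        for i, r in zip(self.ids, self.rows):
            bad = set(r) - ALPHABET - {GAP}
            if bad:
                raise ValueError(f"{i}: illegal characters {sorted(bad)}")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def degapped(self) -> list[Sequence]:
        return [
            Sequence(i, r.replace(GAP, ""), self.family)
            for i, r in zip(self.ids, self.rows)
        ]


def normalize_residues(raw: str, *, allow_gaps: bool = False, context: str = "") -> str:
    """Uppercase, map ambiguity codes to X, normalise gap characters."""
    out = []
    warned = set()
    for ch in raw.upper():
        if ch in _AMBIGUOUS:
            if ch not in warned:
                logger.warning("%s: ambiguity code %s mapped to X", context or "sequence", ch)
                warned.add(ch)
            ch = "X"
        elif ch == ".":
            ch = GAP
        if ch == GAP and not allow_gaps:
            continue
        out.append(ch)
    return "".join(out)


def _locate_bad_char(path: Path, bad: set[str]) -> int:
    """Best-effort line number of the first offending character."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad:
                return lineno
    return 0


def read_fasta(path: str | Path, family: str = "unassigned") -> list[Sequence]:
    """Read a FASTA file into validated :class:`Sequence` objects.

    Gaps are stripped, letters uppercased, record order preserved.  An empty
    file yields an empty list.
    """
    path = Path(path)
    sequences: list[Sequence] = []
    with open(path) as fh:
        first = fh.read(1)
        if first and first not in ">;\n":
            raise ParseError(f"{path}:1: not a FASTA file (expected '>')")
    for rec in SeqIO.parse(path, "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: record with empty header")
        residues = normalize_residues(str(rec.seq), context=rec.id)
        bad = set(residues) - ALPHABET
        if bad:
            lineno = _locate_bad_char(path, bad)
            raise ParseError(
                f"{path}:{lineno}: illegal residue characters {sorted(bad)} in {rec.id}"
            )
        sequences.append(Sequence(rec.id, residues, family))
    return sequences


def write_fasta(sequences: Iterable[Sequence], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_msa(path: str | Path, format: str = "aligned-fasta", family: str = "unassigned") -> MSA:
    """Read an alignment in aligned-FASTA or Clustal format.

    Ragged rows raise an error listing the offending ids.
    """
    path = Path(path)
    if format == "aligned-fasta":
        ids, rows = _read_aligned_fasta(path)
    elif format == "clustal":
        aln = AlignIO.read(path, "clustal")
        ids = [rec.id for rec in aln]
        rows = [normalize_residues(str(rec.seq), allow_gaps=True, context=rec.id) for rec in aln]
    else:
        raise ValueError(f"unknown MSA format {format!r} (use 'aligned-fasta' or 'clustal')")
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        n = len(rows[0])
        offenders = [i for i, r in zip(ids, rows) if len(r) != n]
        raise ParseError(f"{path}: rows differ in aligned length: {offenders}")
    return MSA(tuple(ids), tuple(rows), family)


def _read_aligned_fasta(path: Path) -> tuple[list[str], list[str]]:
    ids, rows = [], []
    for rec in SeqIO.parse(path, "fasta"):
        ids.append(rec.id)
        rows.append(normalize_residues(str(rec.seq), allow_gaps=True, context=rec.id))
    if not ids:
        raise ParseError(f"{path}: no alignment records found")
    return ids, rows


def write_msa(msa: MSA, path: str | Path, format: str = "aligned-fasta") -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(msa.ids, msa.rows)
    ]
    if format == "aligned-fasta":
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
            writer.write_file(records)
    elif format == "clustal":
        AlignIO.write(MultipleSeqAlignment(records), path, "clustal")
    else:
        raise ValueError(f"unknown MSA format {format!r}")
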