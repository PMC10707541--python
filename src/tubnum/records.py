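"""Typed record tables: missense mutations, PTM sites, interaction footprints.

Tables are tab-delimited UTF-8 with a mandatory header row.  Canonical column
orders (used by the writer so that read→write round-trips byte-identically):

* mutation:  family, isotype, species, substitution, phenotype, provenance
* ptm:       family, isotype, species, position, residue, ptm_type, evidence, provenance
* footprint: structure_id, partner, family, positions, provenance

A mutation row's ``substitution`` field is a comma-separated list of
substitutions in ``<from><pos><to>`` notation with native 1-based positions
(e.g. ``R402C``).  ``X`` as the target residue denotes a stop/truncation
(``W407X``); such records are retained but excluded from PTM-ablation logic.
A trailing ``*`` marks a substitution highlighted in the source as hitting a
modification site; it is carried as a flag, never used by the ablation rule
itself.  A bare ``<from><pos>`` token (present verbatim in one source row) is
kept as an *incomplete* substitution with ``to_res=None``.

Footprint ``positions`` are comma lists accepting ``N–M`` ranges (en dash or
hyphen); the writer compacts runs back to en-dash ranges.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence as TSequence

from .utn import UTNLabel, parse_label

__all__ = [
    "Substitution",
    "MutationEntry",
    "MutationRecord",
    "PTMSite",
    "FootprintRecord",
    "RecordTable",
    "SchemaError",
    "parse_substitution",
    "parse_substitution_list",
    "expand_positions",
    "compact_positions",
    "read_table",
    "write_table",
]

_SUB_RE = re.compile(r"^([A-Z])(\d+)([A-Z])?(\*)?$")
_RANGE_RE = re.compile(r"^(\d+)\s*[–-]\s*(\d+)$")

TABLE_COLUMNS = {
    "mutation": ["family", "isotype", "species", "substitution", "phenotype", "provenance"],
    "ptm": ["family", "isotype", "species", "position", "residue", "ptm_type", "evidence", "provenance"],
    "footprint": ["structure_id", "partner", "family", "positions", "provenance"],
}


class SchemaError(ValueError):
    """A table does not match the expected column schema."""


@dataclass(frozen=True)
class Substitution:
    """A single missense substitution in native coordinates."""

    from_res: str
    native_pos: int
    to_res: str | None  # None: incomplete token as printed in the source
    highlighted: bool = False

    def __post_init__(self) -> None:
        if self.native_pos < 1:
            raise ValueError(f"position must be >= 1: {self}")
        if self.to_res == self.from_res and self.to_res != "X":
            raise ValueError(f"synonymous substitution: {self}")

    @property
    def is_truncation(self) -> bool:
        return self.to_res == "X"

    def __str__(self) -> str:
        return f"{self.from_res}{self.native_pos}{self.to_res or ''}" + (
            "*" if self.highlighted else ""
        )


def parse_substitution(text: str) -> Substitution:
    m = _SUB_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse substitution {text!r}")
    from_res, pos, to_res, star = m.groups()
    return Substitution(from_res, int(pos), to_res, highlighted=bool(star))


def parse_substitution_list(text: str) -> tuple[Substitution, ...]:
    """Parse a comma-separated substitution list like ``"C239L*, I152T"``."""
    parts = [p for p in re.split(r"[,;]\s*", text.strip()) if p]
    return tuple(parse_substitution(p) for p in parts)


@dataclass(frozen=True)
class MutationEntry:
    """One table row: an isotype/sample with one or more substitutions."""

    family: str
    isotype: str
    species: str
    substitutions: tuple[Substitution, ...]
    phenotype: str
    provenance: str
    extra: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("every record must carry a provenance string")


@dataclass(frozen=True)
class MutationRecord:
    """A single substitution, optionally annotated with its UTN label."""

    family: str
    isotype: str
    species: str
    native_pos: int
    from_res: str
    to_res: str | None
    phenotype: str
    provenance: str
    utn_label: UTNLabel | None = None
    flag: str = ""  # e.g. "deleted-position" after indexing

    @property
    def is_truncation(self) -> bool:
        return self.to_res == "X"

    def with_label(self, label: UTNLabel | None, flag: str = "") -> "MutationRecord":
        return replace(self, utn_label=label, flag=flag)


def explode_entries(entries: Iterable[MutationEntry]) -> list[MutationRecord]:
    """One :class:`MutationRecord` per substitution of each entry."""
    out = []
    for e in entries:
        for s in e.substitutions:
            out.append(
                MutationRecord(
                    e.family, e.isotype, e.species, s.native_pos,
                    s.from_res, s.to_res, e.phenotype, e.provenance,
                )
            )
    return out


@dataclass(frozen=True)
class PTMSite:
    """A documented modification site, indexed by UTN position."""

    family: str
    isotype: str
    species: str
    utn_position: UTNLabel
    residue: str
    ptm_types: tuple[str, ...]
    evidence: str
    provenance: str

    def __post_init__(self) -> None:
        if self.evidence not in ("validated", "predicted"):
            raise ValueError(f"evidence must be validated|predicted: {self.evidence!r}")
        if not self.provenance:
            raise ValueError("every record must carry a provenance string")


@dataclass(frozen=True)
class FootprintRecord:
    """Residues of one tubulin family within a distance cutoff of a partner."""

    structure_id: str
    partner: str
    family: str
    positions: tuple[int, ...]
    provenance: str
    cutoff: float = 6.0

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("footprint positions must be non-empty")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("positions must be sorted and unique")


@dataclass(frozen=True)
class RecordTable:
    """A homogeneous table of mutation entries, PTM sites, or footprints."""

    kind: str
    rows: tuple

    def __post_init__(self) -> None:
        if self.kind not in TABLE_COLUMNS:
            raise ValueError(f"unknown table kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)


def expand_positions(text: str) -> tuple[int, ...]:
    """Expand ``"104, 108–110, 402"`` to a sorted tuple of integers."""
    out: set[int] = set()
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        m = _RANGE_RE.match(part)
        if m:
            lo, hi = int(m.group(1)), int(m.group(2))
            if hi < lo:
                raise ValueError(f"descending range {part!r}")
            out.update(range(lo, hi + 1))
        else:
            out.add(int(part))
    return tuple(sorted(out))


def compact_positions(positions: TSequence[int]) -> str:
    """Inverse of :func:`expand_positions`: runs become en-dash ranges."""
    pos = sorted(set(positions))
    parts: list[str] = []
    i = 0
    while i < len(pos):
        j = i
        while j + 1 < len(pos) and pos[j + 1] == pos[j] + 1:
            j += 1
        if j > i + 1:
            parts.append(f"{pos[i]}–{pos[j]}")
        elif j == i + 1:
            parts.extend([str(pos[i]), str(pos[j])])
        else:
            parts.append(str(pos[i]))
        i = j + 1
    return ", ".join(parts)


def _row_to_mutation(row: dict, idx: int) -> MutationEntry:
    try:
        subs = parse_substitution_list(row["substitution"])
    except ValueError as exc:
        raise ValueError(f"row {idx}: {exc}") from exc
    extra = tuple(
        (k, v) for k, v in row.items() if k not in TABLE_COLUMNS["mutation"]
    )
    return MutationEntry(
        row["family"], row["isotype"], row["species"],
        subs, row["phenotype"], row["provenance"], extra,
    )


def _row_to_ptm(row: dict, idx: int) -> PTMSite:
    try:
        label = parse_label(row["position"])
    except ValueError as exc:
        raise ValueError(f"row {idx}: {exc}") from exc
    types = tuple(t.strip() for t in row["ptm_type"].split(",") if t.strip())
    return PTMSite(
        row["family"], row["isotype"], row["species"],
        label, row["residue"], types, row["evidence"], row["provenance"],
    )


def _row_to_footprint(row: dict, idx: int) -> FootprintRecord:
    try:
        positions = expand_positions(row["positions"])
    except ValueError as exc:
        raise ValueError(f"row {idx}: {exc}") from exc
    return FootprintRecord(
        row["structure_id"], row["partner"], row["family"], positions,
        row["provenance"],
    )


_PARSERS = {"mutation": _row_to_mutation, "ptm": _row_to_ptm, "footprint": _row_to_footprint}


def read_table(path: str | Path, kind: str) -> RecordTable:
    """Read a TSV record table of the given kind.

    Missing mandatory columns raise :class:`SchemaError`; a row whose
    substitution/position field cannot be parsed raises a row-indexed error.
    Extra columns are preserved (mutation tables keep them as annotations).
    """
    if kind not in TABLE_COLUMNS:
        raise ValueError(f"unknown table kind {kind!r}")
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row is mandatory")
        missing = [c for c in TABLE_COLUMNS[kind] if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing mandatory columns {missing}")
        parser = _PARSERS[kind]
        rows = tuple(parser(row, i) for i, row in enumerate(reader, start=1))
    return RecordTable(kind, rows)


def _mutation_to_row(e: MutationEntry) -> dict:
    row = {
        "family": e.family,
        "isotype": e.isotype,
        "species": e.species,
        "substitution": ", ".join(str(s) for s in e.substitutions),
        "phenotype": e.phenotype,
        "provenance": e.provenance,
    }
    row.update(dict(e.extra))
    return row


def _ptm_to_row(s: PTMSite) -> dict:
    return {
        "family": s.family,
        "isotype": s.isotype,
        "species": s.species,
        "position": str(s.utn_position),
        "residue": s.residue,
        "ptm_type": ", ".join(s.ptm_types),
        "evidence": s.evidence,
        "provenance": s.provenance,
    }


def _footprint_to_row(f: FootprintRecord) -> dict:
    return {
        "structure_id": f.structure_id,
        "partner": f.partner,
        "family": f.family,
        "positions": compact_positions(f.positions),
        "provenance": f.provenance,
    }


_WRITERS = {"mutation": _mutation_to_row, "ptm": _ptm_to_row, "footprint": _footprint_to_row}


def write_table(table: RecordTable, path: str | Path) -> None:
    """Write a record table as TSV in canonical column order."""
    to_row = _WRITERS[table.kind]
    rows = [to_row(r) for r in table.rows]
    columns = list(TABLE_COLUMNS[table.kind])
    for row in rows:
        for k in row:
            if k not in columns:
                columns.append(k)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t", lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)
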