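"""Synthetic tubulin-like families with planted indels and known numbering.

The generator emulates the structure of a tubulin family alignment — many
highly similar sequences of a fixed core length with rare short (1-3
residue) insertions or deletions at known positions — while providing exact
ground truth: every generated sequence comes with the numbering map implied
by the planting, constructed directly (never by alignment).  This makes the
families usable as oracles for the alignment-based numbering pipeline.

Residues are drawn uniformly over the 20 standard amino acids; ground truth
for numbering does not depend on compositional realism.  To keep planted
indels unambiguous under optimal alignment, inserted letters are chosen to
differ from both flanking ancestor residues, deletions never remove a
residue identical to the one just past the deleted block, and positions
flanking an indel are protected from point substitutions in that row.
Identical specs (including the seed) produce byte-identical alignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .numbering import NumberingMap
from .seqio import AMINO_ACIDS, GAP, MSA
from .utn import core_label, insertion_label

__all__ = ["IndelEvent", "SyntheticFamilySpec", "generate_family"]


@dataclass(frozen=True)
class IndelEvent:
    """A planted indel: ``kind`` is 'insertion' (after ``position``, 0 allowed
    for an N-terminal insert) or 'deletion' (of ``position..position+length-1``)."""

    sequence_index: int
    position: int
    length: int
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"indel kind must be insertion|deletion, got {self.kind!r}")
        if self.length < 1:
            raise ValueError("indel length must be >= 1")
        if self.sequence_index < 0:
            raise ValueError("sequence_index must be >= 0")
        min_pos = 0 if self.kind == "insertion" else 1
        if self.position < min_pos:
            raise ValueError(f"{self.kind} position must be >= {min_pos}")


@dataclass(frozen=True)
class SyntheticFamilySpec:
    """Parameters of a synthetic family; same spec (incl. seed) -> same output."""

    n_sequences: int = 12
    core_length: int = 440
    substitution_rate: float = 0.02
    indel_events: tuple[IndelEvent, ...] = ()
    seed: int = 0
    family: str = "unassigned"

    def __post_init__(self) -> None:
        if self.n_sequences < 2:
            raise ValueError("need at least 2 sequences")
        if self.core_length < 2:
            raise ValueError("core_length must be >= 2")
        if not (0.0 <= self.substitution_rate <= 1.0):
            raise ValueError("substitution_rate must be in [0, 1]")
        for ev in self.indel_events:
            if ev.sequence_index >= self.n_sequences:
                raise ValueError(f"event references row {ev.sequence_index} of {self.n_sequences}")
            last = ev.position + (ev.length - 1 if ev.kind == "deletion" else 0)
            if last > self.core_length or (ev.kind == "deletion" and last >= self.core_length):
                raise ValueError(f"indel event {ev} extends beyond the core")
        self._check_overlaps()

    def _check_overlaps(self) -> None:
        by_row: dict[int, list[IndelEvent]] = {}
        for ev in self.indel_events:
            by_row.setdefault(ev.sequence_index, []).append(ev)
        for row, events in by_row.items():
            spans = []
            for ev in events:
                if ev.kind == "deletion":
                    spans.append((ev.position, ev.position + ev.length - 1, ev))
                else:
                    spans.append((ev.position, ev.position, ev))  # anchor only
            spans.sort(key=lambda s: (s[0], s[1]))
            for (a_lo, a_hi, a_ev), (b_lo, b_hi, b_ev) in zip(spans, spans[1:]):
                if b_lo <= a_hi or (
                    a_ev.kind == b_ev.kind == "insertion" and a_lo == b_lo
                ):
                    raise ValueError(
                        f"overlapping indel events in sequence {row}: {a_ev} / {b_ev}"
                    )

    def events_for(self, row: int) -> list[IndelEvent]:
        return sorted(
            (ev for ev in self.indel_events if ev.sequence_index == row),
            key=lambda ev: (ev.position, ev.kind),
        )


def _protected_positions(events: list[IndelEvent], core_length: int) -> set[int]:
    """Core positions shielded from substitutions (in every row) so that the
    consensus around each planted indel equals the ancestor and optimal
    alignment cannot slide a gap within the window."""
    protected: set[int] = set()
    for ev in events:
        lo = ev.position - ev.length - 1
        hi = ev.position + 2 * ev.length + 1
        protected.update(p for p in range(lo, hi + 1) if 1 <= p <= core_length)
    return protected


def _draw_insert(rng: np.random.Generator, length: int, forbidden: set[str]) -> str:
    pool = [aa for aa in AMINO_ACIDS if aa not in forbidden]
    return "".join(rng.choice(pool, size=length))


def generate_family(spec: SyntheticFamilySpec) -> tuple[MSA, dict[str, NumberingMap]]:
    """Generate an aligned family plus per-sequence ground-truth numbering.

    The MSA has one column per core position and one dedicated column block
    per insertion event (occupied only by the inserting row), ordered by
    (anchor, row).  De-gapped rows are exactly the specified sequences, and
    the returned maps are built from the planting, not by alignment.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.core_length
    ancestor = "".join(rng.choice(list(AMINO_ACIDS), size=L))

    # deterministic ancestor-level adjustment: a deletion must not be
    # reproducible one column later (ancestor[p-1] at end of block != next)
    ancestor = list(ancestor)
    for ev in sorted(spec.indel_events, key=lambda e: (e.sequence_index, e.position)):
        if ev.kind != "deletion":
            continue
        p, l = ev.position, ev.length
        # right-shifted alternative (delete p+1..p+l) is score-identical iff
        # a[p] == a[p+l]; left-shifted (delete p-1..p+l-2) iff a[p-1] == a[p+l-1]
        if p + l <= L and ancestor[p - 1] == ancestor[p + l - 1]:
            ancestor[p + l - 1] = _draw_insert(rng, 1, {ancestor[p - 1]})
        if p >= 2 and ancestor[p - 2] == ancestor[p + l - 2]:
            ancestor[p + l - 2] = _draw_insert(
                rng, 1, {ancestor[p - 2], ancestor[p - 1], ancestor[p + l - 1] if p + l <= L else ""}
            )
    ancestor = "".join(ancestor)

    ids = [f"syn{idx:03d}" for idx in range(spec.n_sequences)]
    core_residues: list[list[str | None]] = []  # per row, per core position (None=deleted)
    inserts: dict[tuple[int, int], str] = {}  # (row, anchor) -> inserted letters

    protected = _protected_positions(list(spec.indel_events), L)

    for row in range(spec.n_sequences):
        events = spec.events_for(row)
        residues: list[str | None] = list(ancestor)
        # point substitutions
        mask = rng.random(L) < spec.substitution_rate
        for pos0 in np.nonzero(mask)[0]:
            if (pos0 + 1) in protected:
                continue
            current = residues[pos0]
            residues[pos0] = _draw_insert(rng, 1, {current})
        # planted indels
        for ev in events:
            if ev.kind == "deletion":
                for p in range(ev.position, ev.position + ev.length):
                    residues[p - 1] = None
            else:
                # forbid letters occurring anywhere an optimal alignment could
                # slide the inserted run to (window of +-length around anchor)
                lo = max(0, ev.position - ev.length)
                hi = min(L, ev.position + ev.length + 1)
                forbidden = set(ancestor[lo:hi])
                inserts[(row, ev.position)] = _draw_insert(rng, ev.length, forbidden)
        core_residues.append(residues)

    # assemble alignment columns: insertion blocks between core columns,
    # ordered by (anchor, row)
    blocks = sorted(inserts)  # (row, anchor) sorted by row-major; reorder by anchor
    blocks = sorted(blocks, key=lambda ra: (ra[1], ra[0]))
    rows_out = [[] for _ in range(spec.n_sequences)]

    def emit_blocks(anchor: int) -> None:
        for row, anc in blocks:
            if anc != anchor:
                continue
            letters = inserts[(row, anc)]
            for r in range(spec.n_sequences):
                rows_out[r].append(letters if r == row else GAP * len(letters))

    emit_blocks(0)
    for pos in range(1, L + 1):
        for r in range(spec.n_sequences):
            ch = core_residues[r][pos - 1]
            rows_out[r].append(ch if ch is not None else GAP)
        emit_blocks(pos)

    msa = MSA(tuple(ids), tuple("".join(parts) for parts in rows_out), spec.family)

    # ground-truth numbering maps, built directly from the planting
    truth: dict[str, NumberingMap] = {}
    for row in range(spec.n_sequences):
        entries = []
        deleted = set()
        native = 0

        def emit_insert(anchor: int) -> None:
            nonlocal native
            letters = inserts.get((row, anchor))
            if letters is None:
                return
            for k, ch in enumerate(letters, start=1):
                native += 1
                entries.append((native, ch, insertion_label(anchor, k, len(letters))))

        emit_insert(0)
        for pos in range(1, L + 1):
            ch = core_residues[row][pos - 1]
            if ch is None:
                deleted.add(pos)
            else:
                native += 1
                entries.append((native, ch, core_label(pos)))
            emit_insert(pos)
        truth[ids[row]] = NumberingMap(
            ids[row], spec.family, tuple(entries), frozenset(deleted), 0.0
        )
    return msa, truth
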