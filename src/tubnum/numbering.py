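"""Assign universal tubulin numbering (UTN) labels by consensus alignment.

A query tubulin is aligned end-to-end against its family consensus (global
pairwise alignment, BLOSUM62-derived scores with neutral ``X``, affine gap
penalties).  The alignment induces the numbering:

* a query residue aligned to consensus column *i* takes core label *i*;
* query residues opposite consensus gaps form insertion runs labelled
  ``<anchor>i<ordinal>/<run_length>`` where the anchor is the last preceding
  core position (0 for an N-terminal overhang) — insertions never shift
  downstream numbering;
* consensus columns opposite query gaps are recorded as deleted core
  positions, which renumbers the rest of the query relative to its native
  coordinates (a 2-residue deletion shifts downstream labels by +2);
* residues beyond the last consensus column (the carboxy-terminal tail) are
  labelled as an insertion run anchored at the final core position rather
  than numbered.

The induced map is a bijection between native residue positions and UTN
labels, so equivalent positions can be translated between any two tubulins
numbered against the same family consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from .consensus import ConsensusProfile
from .seqio import Sequence
from .utn import UTNLabel, core_label, format_label, insertion_label, parse_label

__all__ = [
    "AlignmentParams",
    "PairwiseAlignment",
    "NumberingMap",
    "DeletedPositionError",
    "align_to_consensus",
    "build_numbering",
    "number_sequence",
    "equivalent_position",
    "assign_family",
]


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for query-vs-consensus global alignment.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.  End gaps
    are penalised (true end-to-end alignment).  ``X`` (and consensus ``x``
    columns) score 0 against every residue.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


class DeletedPositionError(LookupError):
    """The requested UTN position is deleted in this sequence (no residue)."""


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two equal-length gapped strings plus the alignment score."""

    query: str
    consensus: str
    score: float

    def __post_init__(self) -> None:
        if len(self.query) != len(self.consensus):
            raise ValueError("gapped strings differ in length")


@lru_cache(maxsize=8)
def _neutral_x_matrix(name: str):
    m = substitution_matrices.load(name)
    for ch in m.alphabet:
        m["X", ch] = 0.0
        m[ch, "X"] = 0.0
    return m


@lru_cache(maxsize=8)
def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _neutral_x_matrix(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def align_to_consensus(
    seq: Sequence,
    profile: ConsensusProfile,
    params: AlignmentParams = AlignmentParams(),
) -> PairwiseAlignment:
    """Globally align a query sequence to the family consensus string.

    Lowercase consensus letters score as their uppercase residue; ``x``
    columns score 0 against any residue.  Among co-optimal alignments the
    aligner's canonical first traceback is returned, so results are
    deterministic for fixed parameters.
    """
    if not seq.residues:
        raise ValueError("empty query sequence")
    cons = profile.consensus_upper  # 'x' -> 'X': scores 0 vs anything
    aligner = _make_aligner(params)
    alignment = next(iter(aligner.align(seq.residues, cons)))
    return PairwiseAlignment(str(alignment[0]), str(alignment[1]), float(alignment.score))


@dataclass(frozen=True)
class NumberingMap:
    """Bijection between a query's native positions and UTN labels."""

    query_id: str
    family: str
    entries: tuple[tuple[int, str, UTNLabel], ...]  # (native_pos, residue, label)
    deleted_core: frozenset[int]
    alignment_score: float
    tail_start: int | None = None
    _by_native: dict = field(default_factory=dict, repr=False, compare=False)
    _by_label: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        by_native = {p: (r, lab) for p, r, lab in self.entries}
        by_label = {lab: (p, r) for p, r, lab in self.entries}
        if len(by_native) != len(self.entries) or len(by_label) != len(self.entries):
            raise ValueError("numbering map is not a bijection")
        natives = [p for p, _, _ in self.entries]
        if natives != sorted(natives):
            raise ValueError("native positions must be strictly increasing")
        cores = [lab.core_index for _, _, lab in self.entries if not lab.is_insertion]
        if cores != sorted(cores) or len(cores) != len(set(cores)):
            raise ValueError("core indices must be strictly increasing")
        object.__setattr__(self, "_by_native", by_native)
        object.__setattr__(self, "_by_label", by_label)

    def __len__(self) -> int:
        return len(self.entries)

    def utn_of(self, native_pos: int) -> UTNLabel:
        """UTN label of a native (1-based) residue position."""
        try:
            return self._by_native[native_pos][1]
        except KeyError:
            raise IndexError(
                f"{self.query_id}: native position {native_pos} outside sequence"
            ) from None

    def native_of(self, label: UTNLabel) -> int:
        """Native position carrying the given UTN label.

        Raises :class:`DeletedPositionError` for a core position deleted in
        this sequence, and :class:`KeyError` for a label outside the map.
        """
        hit = self._by_label.get(label)
        if hit is not None:
            return hit[0]
        if not label.is_insertion and label.core_index in self.deleted_core:
            raise DeletedPositionError(
                f"{self.query_id}: no residue at UTN position {label} (deleted)"
            )
        raise KeyError(f"{self.query_id}: UTN label {label} not present")

    def residue_at(self, native_pos: int) -> str:
        return self._by_native[native_pos][0]

    def to_tsv(self, path: str | Path) -> None:
        lines = ["native_pos\tresidue\tutn_label\tnote"]
        for p, r, lab in self.entries:
            if self.tail_start is not None and p >= self.tail_start:
                note = "tail"
            elif lab.is_insertion:
                note = "insertion"
            else:
                note = "core"
            lines.append(f"{p}\t{r}\t{format_label(lab)}\t{note}")
        header = (
            f"# query_id={self.query_id}\tfamily={self.family}\t"
            f"score={self.alignment_score:g}\t"
            f"deleted_core={','.join(map(str, sorted(self.deleted_core)))}\n"
        )
        Path(path).write_text(header + "\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NumberingMap":
        text = Path(path).read_text().splitlines()
        meta = {}
        for kv in text[0].lstrip("# ").split("\t"):
            k, _, v = kv.partition("=")
            meta[k] = v
        entries = []
        tail_start = None
        for line in text[2:]:
            p, r, lab, note = line.split("\t")
            entries.append((int(p), r, parse_label(lab)))
            if note == "tail" and tail_start is None:
                tail_start = int(p)
        deleted = frozenset(
            int(x) for x in meta.get("deleted_core", "").split(",") if x
        )
        return cls(
            meta["query_id"], meta["family"], tuple(entries), deleted,
            float(meta.get("score", "nan")), tail_start,
        )


def build_numbering(
    alignment: PairwiseAlignment, query_id: str, family: str
) -> NumberingMap:
    """Translate a query-vs-consensus alignment into a :class:`NumberingMap`."""
    q, c = alignment.query, alignment.consensus
    n_cons = sum(1 for ch in c if ch != "-")
    entries: list[tuple[int, str, UTNLabel]] = []
    deleted: set[int] = set()
    native = 0
    core = 0  # last consensus column consumed
    run: list[tuple[int, str]] = []  # pending insertion run (native, residue)

    def flush_run(anchor: int) -> None:
        if not run:
            return
        length = len(run)
        for k, (pos, res) in enumerate(run, start=1):
            entries.append((pos, res, insertion_label(anchor, k, length)))
        run.clear()

    for qc, cc in zip(q, c):
        if qc != "-" and cc != "-":
            flush_run(core)
            native += 1
            core += 1
            entries.append((native, qc, core_label(core)))
        elif qc != "-":  # insertion in query
            native += 1
            run.append((native, qc))
        elif cc != "-":  # deletion in query
            flush_run(core)
            core += 1
            deleted.add(core)
    tail_start = None
    if run and core == n_cons:
        tail_start = run[0][0]
    flush_run(core)
    return NumberingMap(
        query_id, family, tuple(entries), frozenset(deleted),
        alignment.score, tail_start,
    )


def number_sequence(
    seq: Sequence,
    profile: ConsensusProfile,
    params: AlignmentParams = AlignmentParams(),
) -> NumberingMap:
    """Align a sequence to its family consensus and number it."""
    aln = align_to_consensus(seq, profile, params)
    return build_numbering(aln, seq.id, profile.family)


def equivalent_position(
    map_a: NumberingMap, map_b: NumberingMap, native_pos_in_a: int
) -> int | None:
    """Translate a native position of sequence A into sequence B via UTN.

    Returns ``None`` when the corresponding position is deleted in B (or,
    for an insertion label, when B has no insertion with identical anchor
    and ordinal).  Raises on family mismatch or out-of-range positions.
    """
    if map_a.family != map_b.family:
        raise ValueError(
            f"family mismatch: {map_a.family} vs {map_b.family}"
        )
    label = map_a.utn_of(native_pos_in_a)
    try:
        return map_b.native_of(label)
    except (DeletedPositionError, KeyError):
        return None


def assign_family(
    seq: Sequence,
    profiles: dict[str, ConsensusProfile],
    params: AlignmentParams = AlignmentParams(),
    margin: float = 0.0,
) -> tuple[str, dict[str, float]]:
    """Assign a sequence to the best-scoring family consensus.

    Returns ``(family, per-family scores)``.  When the top score does not
    exceed the runner-up by more than ``margin`` (exact ties included), the
    family is ``"unassigned"``.
    """
    if not profiles:
        raise ValueError("at least one consensus profile is required")
    scores = {
        fam: align_to_consensus(seq, prof, params).score
        for fam, prof in profiles.items()
    }
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) > 1 and ranked[0][1] - ranked[1][1] <= margin:
        return "unassigned", scores
    return ranked[0][0], scores
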