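"""Family consensus profiles.

A consensus profile is built from a family MSA in three steps:

1. *insertion-column removal*: alignment columns occupied by fewer than a
   threshold fraction of rows (default 0.5) are treated as uncommon
   insertions and dropped, so the consensus coordinate system reflects the
   common core of the family;
2. *consensus calling*: per kept column, the plurality residue among non-gap
   rows is emitted UPPERCASE when its frequency reaches the upper threshold
   (default 0.5), lowercase between the lower (default 0.25) and upper
   thresholds, and ``x`` when no residue reaches the lower threshold;
3. *truncation*: profiles are cut at 440 columns, excluding the heterogeneous
   carboxy-terminal tail from the universal coordinate system.

The numeric per-column frequency vectors (gap-excluded, renormalised) double
as a conservation profile, and each column carries its Lesk colour class.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path

from .seqio import GAP, MSA

MAX_CORE_LENGTH = 440

#: Lesk colour classes for amino-acid properties.
LESK_CLASSES = {
    "small-nonpolar": set("GAST"),
    "hydrophobic": set("CVILPFYMW"),
    "polar": set("NQH"),
    "negative": set("DE"),
    "positive": set("KR"),
}
_RESIDUE_TO_CLASS = {aa: name for name, aas in LESK_CLASSES.items() for aa in aas}

__all__ = [
    "MAX_CORE_LENGTH",
    "LESK_CLASSES",
    "ConsensusProfile",
    "ConservationColumn",
    "lesk_class",
    "remove_insertion_columns",
    "call_consensus",
    "truncate_profile",
    "build_profile",
]


def lesk_class(residue: str) -> str:
    """Lesk colour class of a residue; 'unknown' for X or anything else."""
    return _RESIDUE_TO_CLASS.get(residue.upper(), "unknown")


@dataclass(frozen=True)
class ConservationColumn:
    """Per-position conservation summary (numeric sequence-logo row)."""

    utn_index: int
    frequencies: dict[str, float]
    top_residue: str
    top_fraction: float


@dataclass(frozen=True)
class ConsensusProfile:
    """A family consensus with per-column frequencies and confidence case."""

    family: str
    consensus: str
    column_freqs: tuple[dict[str, float], ...]
    removed_columns: tuple[int, ...]
    n_sequences: int
    color_class: tuple[str, ...]
    upper_threshold: float = 0.5
    lower_threshold: float = 0.25

    def __post_init__(self) -> None:
        n = len(self.consensus)
        if not (n == len(self.column_freqs) == len(self.color_class)):
            raise ValueError("consensus/freqs/color lengths disagree")
        for j, freqs in enumerate(self.column_freqs):
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"column {j + 1}: frequencies sum to {total}")

    def __len__(self) -> int:
        return len(self.consensus)

    @property
    def consensus_upper(self) -> str:
        """Consensus with confidence case stripped ('x' kept as 'X')."""
        return self.consensus.upper()

    def conservation(self) -> list[ConservationColumn]:
        cols = []
        for j, freqs in enumerate(self.column_freqs, start=1):
            top = max(sorted(freqs), key=freqs.__getitem__)
            cols.append(ConservationColumn(j, dict(freqs), top, freqs[top]))
        return cols

    def to_json(self, path: str | Path) -> None:
        payload = {
            "family": self.family,
            "consensus": self.consensus,
            "upper_threshold": self.upper_threshold,
            "lower_threshold": self.lower_threshold,
            "n_sequences": self.n_sequences,
            "removed_columns": list(self.removed_columns),
            "columns": [
                {
                    "utn_index": c.utn_index,
                    "top_residue": c.top_residue,
                    "top_fraction": round(c.top_fraction, 6),
                    "color_class": self.color_class[c.utn_index - 1],
                    "frequencies": {k: round(v, 6) for k, v in sorted(c.frequencies.items())},
                }
                for c in self.conservation()
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ConsensusProfile":
        payload = json.loads(Path(path).read_text())
        freqs = tuple(
            {k: float(v) for k, v in col["frequencies"].items()}
            for col in payload["columns"]
        )
        # renormalise: round-tripping through rounded JSON must not trip the invariant
        freqs = tuple(
            {k: v / sum(col.values()) for k, v in col.items()} for col in freqs
        )
        colors = tuple(col["color_class"] for col in payload["columns"])
        return cls(
            payload["family"], payload["consensus"], freqs,
            tuple(payload["removed_columns"]), payload["n_sequences"], colors,
            payload["upper_threshold"], payload["lower_threshold"],
        )

    def conservation_tsv(self, path: str | Path) -> None:
        lines = ["utn_index\ttop_residue\ttop_fraction\tcolor_class"]
        for c in self.conservation():
            lines.append(
                f"{c.utn_index}\t{c.top_residue}\t{c.top_fraction:.6f}\t{self.color_class[c.utn_index - 1]}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def remove_insertion_columns(
    msa: MSA, occupancy_threshold: float = 0.5
) -> tuple[MSA, tuple[int, ...]]:
    """Drop alignment columns occupied by < threshold fraction of rows.

    Returns the core MSA and the removed original column indices (0-based,
    ascending).  Kept columns preserve their order.
    """
    if not (0.0 < occupancy_threshold <= 1.0):
        raise ValueError(f"occupancy_threshold must be in (0, 1], got {occupancy_threshold}")
    n = msa.n_rows
    removed = []
    kept = []
    for j in range(msa.n_cols):
        col = msa.column(j)
        occupancy = sum(1 for ch in col if ch != GAP) / n
        (kept if occupancy >= occupancy_threshold else removed).append(j)
    rows = tuple("".join(row[j] for j in kept) for row in msa.rows)
    core = MSA(msa.ids, rows, msa.family)
    return core, tuple(removed)


def call_consensus(
    core_msa: MSA,
    upper_threshold: float = 0.5,
    lower_threshold: float = 0.25,
    family: str | None = None,
    removed_columns: tuple[int, ...] = (),
) -> ConsensusProfile:
    """Call the per-column plurality consensus with confidence case.

    Plurality ties are broken alphabetically (A < C < D < ... < Y) so calls
    are deterministic.  Frequencies are computed over non-gap rows only.
    """
    if not (upper_threshold > lower_threshold > 0):
        raise ValueError(
            f"need upper > lower > 0, got upper={upper_threshold}, lower={lower_threshold}"
        )
    letters: list[str] = []
    freqs: list[dict[str, float]] = []
    colors: list[str] = []
    for j in range(core_msa.n_cols):
        col = [ch for ch in core_msa.column(j) if ch != GAP]
        if not col:
            raise ValueError(f"column {j} is all-gap; remove insertion columns first")
        counts = Counter(col)
        total = len(col)
        # alphabetical tie-break: sort candidates, take max by count
        top = max(sorted(counts), key=counts.__getitem__)
        f = counts[top] / total
        if f >= upper_threshold:
            letters.append(top.upper())
        elif f >= lower_threshold:
            letters.append(top.lower())
        else:
            letters.append("x")
        freqs.append({aa: c / total for aa, c in sorted(counts.items())})
        colors.append(lesk_class(top))
    return ConsensusProfile(
        family or core_msa.family,
        "".join(letters),
        tuple(freqs),
        tuple(removed_columns),
        core_msa.n_rows,
        tuple(colors),
        upper_threshold,
        lower_threshold,
    )


def truncate_profile(profile: ConsensusProfile, max_len: int = MAX_CORE_LENGTH) -> ConsensusProfile:
    """Cut a profile to its first ``max_len`` columns (idempotent)."""
    if max_len < 1:
        raise ValueError("max_len must be positive")
    if len(profile) <= max_len:
        return profile
    return replace(
        profile,
        consensus=profile.consensus[:max_len],
        column_freqs=profile.column_freqs[:max_len],
        color_class=profile.color_class[:max_len],
    )


def build_profile(
    msa: MSA,
    family: str | None = None,
    occupancy_threshold: float = 0.5,
    upper_threshold: float = 0.5,
    lower_threshold: float = 0.25,
    max_len: int = MAX_CORE_LENGTH,
) -> ConsensusProfile:
    """Full pipeline: remove insertion columns, call consensus, truncate."""
    core, removed = remove_insertion_columns(msa, occupancy_threshold)
    profile = call_consensus(core, upper_threshold, lower_threshold, family, removed)
    return truncate_profile(profile, max_len)


def profile_from_string(consensus: str, family: str = "unassigned") -> ConsensusProfile:
    """Wrap a bare consensus string (case-sensitive, 'x' allowed) as a profile.

    Every column gets frequency 1.0 for its residue; 'x' columns carry a
    placeholder frequency on 'X'.  Useful for loading a consensus published
    as a plain sequence rather than rebuilding it from an MSA.
    """
    freqs = tuple(
        {("X" if ch == "x" else ch.upper()): 1.0} for ch in consensus
    )
    colors = tuple(lesk_class(ch) for ch in consensus)
    return ConsensusProfile(family, consensus, freqs, (), 1, colors)
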