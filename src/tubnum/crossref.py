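"""Cross-referencing UTN-indexed mutations, PTM sites, and footprints.

All joins are on (family, core UTN position); insertion-labelled positions
join only on exact (anchor, ordinal) label equality.  Distinct *sites* are
counted as unique (family, UTN core index) pairs regardless of isotype.
Duplicate records from different sources are kept as separate rows, and
every output row carries the provenance of all records it joins.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .consensus import ConsensusProfile
from .numbering import DeletedPositionError, NumberingMap
from .ptm import ablated_ptms
from .records import (
    FootprintRecord,
    MutationEntry,
    MutationRecord,
    PTMSite,
    RecordTable,
    explode_entries,
)
from .utn import UTNLabel, core_label, format_label

__all__ = [
    "CrossRefReport",
    "index_by_utn",
    "index_records",
    "mutations_in_footprint",
    "mutations_ablating_ptms",
    "ablations_by_entry",
    "position_summary",
]


@dataclass(frozen=True)
class CrossRefReport:
    """Joined rows of one report kind, with provenance carried through."""

    kind: str  # mutation×footprint | mutation×ptm | position_summary
    rows: tuple[dict, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("mutation×footprint", "mutation×ptm", "position_summary"):
            raise ValueError(f"unknown report kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.rows))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def distinct_sites(self) -> set[tuple[str, int]]:
        """Unique (family, core UTN index) pairs among the joined rows."""
        return {
            (row["family"], row["utn_position"])
            for row in self.rows
            if isinstance(row.get("utn_position"), int)
        }


def index_by_utn(
    records: RecordTable | list[MutationRecord],
    numbering: dict[str, NumberingMap] | None = None,
) -> list[MutationRecord]:
    """Annotate mutation records with UTN labels.

    ``numbering`` maps isotype name to a :class:`NumberingMap`.  Isotypes
    without a map are treated as already UTN-indexed (identity: native
    position == core UTN index), the common case for human α/β isotypes with
    no indels relative to the consensus.  Records whose native position is
    deleted relative to the consensus are flagged, not dropped.
    """
    if isinstance(records, RecordTable):
        if records.kind != "mutation":
            raise ValueError(f"expected a mutation table, got {records.kind!r}")
        flat = explode_entries(list(records.rows))
    else:
        flat = list(records)
    numbering = numbering or {}
    out: list[MutationRecord] = []
    for rec in flat:
        nmap = numbering.get(rec.isotype)
        if nmap is None:
            out.append(rec.with_label(core_label(rec.native_pos)))
            continue
        try:
            label = nmap.utn_of(rec.native_pos)
        except IndexError:
            out.append(rec.with_label(None, flag="outside-sequence"))
            continue
        expected = nmap.residue_at(rec.native_pos)
        flag = "" if expected == rec.from_res else f"residue-mismatch:{expected}"
        out.append(rec.with_label(label, flag=flag))
    return out


def index_records(
    table: RecordTable, numbering: dict[str, NumberingMap] | None = None
) -> list[MutationRecord]:
    """Alias of :func:`index_by_utn` for RecordTable input."""
    return index_by_utn(table, numbering)


def _require_indexed(mutations: list[MutationRecord]) -> None:
    missing = sorted({m.isotype for m in mutations if m.utn_label is None and m.flag == ""})
    if missing:
        raise ValueError(f"mutation records lack UTN labels for isotypes: {missing}")


def mutations_in_footprint(
    mutations: list[MutationRecord],
    footprints: RecordTable | list[FootprintRecord],
) -> CrossRefReport:
    """One row per (mutation, footprint) pair sharing family and UTN position."""
    _require_indexed(mutations)
    fps = list(footprints.rows) if isinstance(footprints, RecordTable) else list(footprints)
    rows = []
    for fp in fps:
        fp_positions = set(fp.positions)
        for mut in mutations:
            label = mut.utn_label
            if label is None or label.is_insertion:
                continue
            if mut.family != fp.family:
                continue
            if label.core_index in fp_positions:
                rows.append(
                    {
                        "family": mut.family,
                        "utn_position": label.core_index,
                        "utn_label": format_label(label),
                        "isotype": mut.isotype,
                        "species": mut.species,
                        "substitution": f"{mut.from_res}{mut.native_pos}{mut.to_res or ''}",
                        "phenotype": mut.phenotype,
                        "partner": fp.partner,
                        "structure_id": fp.structure_id,
                        "mutation_provenance": mut.provenance,
                        "footprint_provenance": fp.provenance,
                    }
                )
    return CrossRefReport("mutation×footprint", tuple(rows))


def mutations_ablating_ptms(
    mutations: list[MutationRecord],
    ptm_sites: RecordTable | list[PTMSite],
    rule: str = "site-specific",
) -> CrossRefReport:
    """Rows of (mutation, site, ablated PTM names); truncations excluded."""
    _require_indexed(mutations)
    sites = list(ptm_sites.rows) if isinstance(ptm_sites, RecordTable) else list(ptm_sites)
    rows = []
    for site in sites:
        for mut in mutations:
            if mut.utn_label is None or mut.family != site.family:
                continue
            if mut.isotype != site.isotype and site.isotype != "*":
                continue
            if mut.utn_label != site.utn_position:
                continue
            if mut.to_res in (None, "X"):
                continue  # truncations/incomplete records never enter ablation calls
            ablated = ablated_ptms(mut, site, rule=rule)
            if not ablated:
                continue
            rows.append(
                {
                    "family": mut.family,
                    "utn_position": (
                        site.utn_position.core_index
                        if not site.utn_position.is_insertion
                        else format_label(site.utn_position)
                    ),
                    "utn_label": format_label(site.utn_position),
                    "isotype": mut.isotype,
                    "species": mut.species,
                    "substitution": f"{mut.from_res}{mut.native_pos}{mut.to_res}",
                    "ablated_ptms": ", ".join(sorted(ablated)),
                    "evidence": site.evidence,
                    "phenotype": mut.phenotype,
                    "mutation_provenance": mut.provenance,
                    "site_provenance": site.provenance,
                }
            )
    return CrossRefReport("mutation×ptm", tuple(rows))


def ablations_by_entry(
    entries: RecordTable | list[MutationEntry],
    ptm_sites: RecordTable | list[PTMSite],
    rule: str = "site-specific",
) -> list[tuple[MutationEntry, frozenset[str]]]:
    """Per table entry (one isotype/sample, possibly many substitutions):
    the union of PTM types its substitutions ablate.

    This is the entry-level summary behind statements like "17 of 21 mutant
    isotypes harbor changes that eliminate at least one PTM site".
    """
    rows = list(entries.rows) if isinstance(entries, RecordTable) else list(entries)
    sites = list(ptm_sites.rows) if isinstance(ptm_sites, RecordTable) else list(ptm_sites)
    by_key: dict[tuple[str, str, UTNLabel], list[PTMSite]] = {}
    for site in sites:
        by_key.setdefault((site.family, site.isotype, site.utn_position), []).append(site)
    out = []
    for entry in rows:
        lost: set[str] = set()
        for sub in entry.substitutions:
            if sub.to_res in (None, "X"):
                continue
            label = core_label(sub.native_pos)  # entries here carry UTN-aligned positions
            for site in by_key.get((entry.family, entry.isotype, label), []):
                lost |= ablated_ptms(sub, site, rule=rule)
        out.append((entry, frozenset(lost)))
    return out


def position_summary(
    family: str,
    profile: ConsensusProfile,
    mutations: list[MutationRecord] | None = None,
    ptm_sites: list[PTMSite] | RecordTable | None = None,
    footprints: list[FootprintRecord] | RecordTable | None = None,
) -> pd.DataFrame:
    """Per core position 1..len(profile): consensus residue, flags and counts.

    Mirrors the per-position mutation/PTM/interaction asterisk rows printed
    under the family conservation profiles.
    """
    mutations = mutations or []
    sites = list(ptm_sites.rows) if isinstance(ptm_sites, RecordTable) else list(ptm_sites or [])
    fps = list(footprints.rows) if isinstance(footprints, RecordTable) else list(footprints or [])

    n = len(profile)
    mut_counts = [0] * (n + 1)
    for m in mutations:
        if m.family != family or m.utn_label is None or m.utn_label.is_insertion:
            continue
        idx = m.utn_label.core_index
        if 1 <= idx <= n:
            mut_counts[idx] += 1
    ptm_counts = [0] * (n + 1)
    for s in sites:
        if s.family != family or s.utn_position.is_insertion:
            continue
        idx = s.utn_position.core_index
        if 1 <= idx <= n:
            ptm_counts[idx] += 1
    fp_counts = [0] * (n + 1)
    for fp in fps:
        if fp.family != family:
            continue
        for pos in fp.positions:
            if 1 <= pos <= n:
                fp_counts[pos] += 1

    return pd.DataFrame(
        {
            "utn_position": range(1, n + 1),
            "consensus": list(profile.consensus),
            "has_mutation": [mut_counts[i] > 0 for i in range(1, n + 1)],
            "has_ptm": [ptm_counts[i] > 0 for i in range(1, n + 1)],
            "has_interaction": [fp_counts[i] > 0 for i in range(1, n + 1)],
            "n_mutations": mut_counts[1:],
            "n_ptms": ptm_counts[1:],
            "n_interactions": fp_counts[1:],
        }
    )
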