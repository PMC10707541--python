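"""Post-translational modification (PTM) types and the ablation rule.

Each PTM type modifies a fixed set of residues: acetylation (K),
glutamylation (E), glycylation (E), malonylation (K), methylation (H, K, R),
nitrosylation (C), palmitoylation (C), phosphorylation (S, T, Y),
succinylation (K), SUMOylation (K), ubiquitination (K) and O-linked
glycosylation (S, T).  Detyrosination/retyrosination and the
polyglutamylation/polyglycylation of the carboxy-terminal tail are listed as
types but are never attached to UTN positions: the tail lies beyond the
consensus core (positions 1-440) and is excluded from position-level
indexing.

The default ablation rule is *site-specific*: any missense change at a
documented modification site ablates all of the site's modifications, even a
chemically conservative one (T→S at a phospho-site, K→R at an
acetylation/ubiquitination site), because the documented site itself — the
residue the modifying enzyme was shown or predicted to act on — is lost.  A
*chemistry-preserving* variant (a substitution only ablates the modification
types whose modifiable-residue set excludes the new residue) is available
for sensitivity analysis.  Truncations (target residue ``X``) are excluded
from ablation calls upstream.  Gains of a potentially modifiable residue
(e.g. S239C creating a cysteine) are reported as informational notes only.
"""

from __future__ import annotations

import logging
from typing import Iterable

from .records import MutationRecord, PTMSite, Substitution

logger = logging.getLogger(__name__)

#: PTM type -> residues it can modify.
MODIFIABLE_RESIDUES: dict[str, frozenset[str]] = {
    "acetylation": frozenset("K"),
    "glutamylation": frozenset("E"),
    "glycylation": frozenset("E"),
    "malonylation": frozenset("K"),
    "methylation": frozenset("HKR"),
    "nitrosylation": frozenset("C"),
    "palmitoylation": frozenset("C"),
    "phosphorylation": frozenset("STY"),
    "succinylation": frozenset("K"),
    "SUMOylation": frozenset("K"),
    "ubiquitination": frozenset("K"),
    "O-glycosylation": frozenset("ST"),
    # mono-ADP-ribosylation acceptors; chemistry-based (common acceptor residues)
    "MARylation": frozenset("EDRSK"),
    # arginine -> citrulline, chemically forced
    "citrullination": frozenset("R"),
}

#: Abbreviations used in the printed synthesis tables.
PTM_ABBREVIATIONS = {
    "PHO": "phosphorylation",
    "ACE": "acetylation",
    "UBI": "ubiquitination",
    "SMO": "SUMOylation",
    "NIT": "nitrosylation",
    "PAL": "palmitoylation",
    "MET": "methylation",
    "GLU": "glutamylation",
    "GLY": "glycylation",
    "MAL": "malonylation",
    "SUC": "succinylation",
    "OGL": "O-glycosylation",
}

ABLATION_RULES = ("site-specific", "chemistry-preserving")

__all__ = [
    "MODIFIABLE_RESIDUES",
    "PTM_ABBREVIATIONS",
    "ABLATION_RULES",
    "modifiable_residues",
    "canonical_ptm_name",
    "validate_site",
    "ablated_ptms",
    "gained_residue_note",
]


def canonical_ptm_name(name: str) -> str:
    """Resolve an abbreviation or case variant to the canonical PTM name."""
    if name in MODIFIABLE_RESIDUES:
        return name
    upper = name.upper()
    if upper in PTM_ABBREVIATIONS:
        return PTM_ABBREVIATIONS[upper]
    for known in MODIFIABLE_RESIDUES:
        if known.lower() == name.lower():
            return known
    raise KeyError(
        f"unknown PTM type {name!r}; valid names: {sorted(MODIFIABLE_RESIDUES)}"
    )


def modifiable_residues(ptm_name: str) -> frozenset[str]:
    """Residues a PTM type can modify (e.g. phosphorylation -> {S, T, Y})."""
    return MODIFIABLE_RESIDUES[canonical_ptm_name(ptm_name)]


def validate_site(site: PTMSite) -> None:
    """Check that the site's residue is modifiable by all its PTM types."""
    for name in site.ptm_types:
        allowed = modifiable_residues(name)
        if site.residue not in allowed:
            raise ValueError(
                f"{site.isotype} {site.utn_position}: residue {site.residue} "
                f"is not modifiable by {canonical_ptm_name(name)} ({sorted(allowed)})"
            )


def ablated_ptms(
    mutation: MutationRecord | Substitution,
    site: PTMSite,
    rule: str = "site-specific",
) -> frozenset[str]:
    """PTM types of ``site`` ablated by a missense substitution at that site.

    The caller must already have joined mutation and site on (family, UTN
    position); a truncation or incomplete substitution must be filtered out
    upstream and is rejected here.
    """
    if rule not in ABLATION_RULES:
        raise ValueError(f"unknown ablation rule {rule!r}; choose from {ABLATION_RULES}")
    to_res = mutation.to_res
    from_res = mutation.from_res
    if to_res is None or to_res == "X":
        raise ValueError(
            f"truncation/incomplete substitution {from_res}...{to_res} must be "
            "excluded before calling the ablation rule"
        )
    if isinstance(mutation, MutationRecord):
        if mutation.utn_label is not None and mutation.utn_label != site.utn_position:
            raise ValueError(
                f"position mismatch: mutation at {mutation.utn_label}, "
                f"site at {site.utn_position} — pre-join on UTN"
            )
        if mutation.family != site.family:
            raise ValueError(
                f"family mismatch: {mutation.family} vs {site.family}"
            )
    if to_res == from_res:
        return frozenset()
    names = frozenset(canonical_ptm_name(t) for t in site.ptm_types)
    if rule == "site-specific":
        return names
    return frozenset(
        n for n in names if to_res not in modifiable_residues(n)
    )


def gained_residue_note(mutation: MutationRecord | Substitution) -> list[str]:
    """Informational only: PTM types whose modifiable set gains the new residue."""
    if mutation.to_res in (None, "X"):
        return []
    return sorted(
        name
        for name, allowed in MODIFIABLE_RESIDUES.items()
        if mutation.to_res in allowed and mutation.from_res not in allowed
    )
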