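"""Interaction footprints from macromolecular structures.

A *footprint* is the set of residues of a target chain having at least one
heavy atom within a distance cutoff (default 6.0 Å, boundary inclusive) of
any heavy atom of a partner selection — another chain, or a ligand selected
by residue name (GTP, GDP, paclitaxel, ...).  Selections are by-residue:
one contact atom pulls in the whole residue, matching how printed footprint
lists are reported.

Structure files (PDB or mmCIF) are read with gemmi.  Hydrogens are dropped,
waters are excluded by default, only the highest-occupancy alternative
conformation is kept, and only the first model of an ensemble is used.
Author residue numbering is preserved, since published tubulin footprints
use biological residue numbers.

The neighbour search uses a k-d tree over partner atoms; an all-pairs scan
over the same selections gives identical results and serves as the test
oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

import gemmi

from .consensus import ConsensusProfile
from .numbering import AlignmentParams, NumberingMap, number_sequence
from .records import FootprintRecord
from .seqio import ALPHABET, Sequence

logger = logging.getLogger(__name__)

#: Residue names treated as solvent and excluded from all selections.
WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: Common monatomic ions, excluded from partner selections by default.
ION_NAMES = {"NA", "K", "MG", "CA", "ZN", "CL", "MN", "FE", "CU", "NI", "CO", "CD", "IOD", "BR"}

__all__ = [
    "StructureModel",
    "StructureChain",
    "StructureResidue",
    "NoContactResult",
    "load_structure",
    "footprint",
    "chain_sequence",
    "chain_numbering",
]


@dataclass(frozen=True)
class StructureResidue:
    """One residue: author number, residue name, heavy-atom coordinates."""

    author_number: int
    name: str
    elements: tuple[str, ...]
    coords: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.coords, dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite coordinates in residue {self.name} {self.author_number}")


@dataclass(frozen=True)
class StructureChain:
    chain_id: str
    role: str  # alpha | beta | gamma | partner | ligand | other
    residues: tuple[StructureResidue, ...]

    def atom_coords(self, residue_names: set[str] | None = None) -> np.ndarray:
        coords = [
            xyz
            for res in self.residues
            if residue_names is None or res.name in residue_names
            for xyz in res.coords
        ]
        return np.asarray(coords, dtype=float).reshape(-1, 3)


@dataclass(frozen=True)
class StructureModel:
    structure_id: str
    chains: tuple[StructureChain, ...]

    def chain(self, chain_id: str) -> StructureChain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"{self.structure_id}: no chain {chain_id!r}")


@dataclass(frozen=True)
class NoContactResult:
    """Explicit result for an empty footprint (no residue within cutoff)."""

    structure_id: str
    partner: str
    family: str
    cutoff: float


def _pick_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: the highest-occupancy altloc (ties: first)."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    # preserve file order of first appearance
    seen = set()
    ordered = []
    for atom in residue:
        if atom.name not in seen:
            seen.add(atom.name)
            ordered.append(best[atom.name])
    return ordered


def load_structure(
    path: str | Path,
    format: str | None = None,
    include_waters: bool = False,
    chain_roles: dict[str, str] | None = None,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Heavy atoms only; waters excluded unless requested; highest-occupancy
    altloc kept; first model only (logged for ensembles).  ``format`` is
    inferred from the suffix when not given.  ``chain_roles`` optionally
    assigns roles (alpha/beta/gamma/partner/ligand) by chain id.
    """
    path = Path(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if format == "pdb":
        st = gemmi.read_pdb(str(path))
    elif format == "mmcif":
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    else:
        raise ValueError(f"unknown structure format {format!r} (use 'pdb' or 'mmcif')")
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: structure contains no models")
    if len(st) > 1:
        logger.info("%s: ensemble with %d models, using the first", path.name, len(st))
    model = st[0]
    chain_roles = chain_roles or {}
    chains = []
    for chain in model:
        residues = []
        for res in chain:
            if not include_waters and res.name in WATER_NAMES:
                continue
            atoms = [a for a in _pick_altlocs(res) if a.element.name != "H"]
            if not atoms:
                continue
            if res.seqid.num is None:
                raise ValueError(
                    f"{path}: chain {chain.name} residue {res.name} lacks an author number"
                )
            residues.append(
                StructureResidue(
                    res.seqid.num,
                    res.name,
                    tuple(a.element.name for a in atoms),
                    tuple((a.pos.x, a.pos.y, a.pos.z) for a in atoms),
                )
            )
        if not residues:
            continue
        numbers = [r.author_number for r in residues]
        if len(numbers) != len(set(numbers)):
            dupes = sorted({n for n in numbers if numbers.count(n) > 1})
            raise ValueError(
                f"{path}: chain {chain.name} has duplicate residue numbers {dupes}"
            )
        chains.append(
            StructureChain(chain.name, chain_roles.get(chain.name, "other"), tuple(residues))
        )
    return StructureModel(path.stem if st.name in ("", "XXXX") else st.name.lower(), tuple(chains))


def _partner_coords(
    model: StructureModel,
    partner_selector: str,
    exclude_ions: bool,
) -> np.ndarray:
    """Atom coordinates of a partner chain id, or of a ligand by residue name."""
    chain_ids = {c.chain_id for c in model.chains}
    if partner_selector in chain_ids:
        return model.chain(partner_selector).atom_coords()
    # ligand selection by residue name across all chains
    name = partner_selector.upper()
    if exclude_ions and name in ION_NAMES:
        logger.warning("partner %s is an ion; selecting it anyway as explicitly requested", name)
    coords = [
        xyz
        for ch in model.chains
        for res in ch.residues
        if res.name.upper() == name
        for xyz in res.coords
    ]
    return np.asarray(coords, dtype=float).reshape(-1, 3)


def footprint(
    model: StructureModel,
    target_chain: str,
    partner_selector: str,
    cutoff: float = 6.0,
    partner_name: str | None = None,
    boundary: str = "inclusive",
) -> FootprintRecord | NoContactResult:
    """Residues of ``target_chain`` within ``cutoff`` Å of the partner.

    ``partner_selector`` is a chain id or a ligand residue name.  A residue
    is included iff the minimum heavy-atom pair distance to the partner
    selection satisfies the boundary rule (inclusive ``<=`` by default).
    Returns an explicit :class:`NoContactResult` when nothing is in range.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if boundary not in ("inclusive", "exclusive"):
        raise ValueError(f"boundary must be inclusive|exclusive, got {boundary!r}")
    target = model.chain(target_chain)
    if not target.residues:
        raise ValueError(f"empty target selection: chain {target_chain}")
    partner_xyz = _partner_coords(model, partner_selector, exclude_ions=True)
    if partner_xyz.size == 0:
        raise ValueError(f"empty partner selection: {partner_selector!r}")
    tree = cKDTree(partner_xyz)
    positions = []
    for res in target.residues:
        coords = np.asarray(res.coords, dtype=float)
        dmin = tree.query(coords, k=1)[0].min()
        hit = dmin <= cutoff if boundary == "inclusive" else dmin < cutoff
        if hit:
            positions.append(res.author_number)
    family = target.role if target.role in ("alpha", "beta", "gamma") else "unassigned"
    if not positions:
        logger.warning(
            "%s: no %s residue within %.1f Å of %s",
            model.structure_id, target_chain, cutoff, partner_selector,
        )
        return NoContactResult(model.structure_id, partner_name or partner_selector, family, cutoff)
    return FootprintRecord(
        model.structure_id,
        partner_name or partner_selector,
        family,
        tuple(sorted(set(positions))),
        f"PDB {model.structure_id}",
        cutoff,
    )


_ONE_LETTER_OVERRIDES = {"MSE": "M"}


def chain_sequence(chain: StructureChain) -> tuple[str, list[int]]:
    """One-letter sequence of a protein chain plus author numbers per residue.

    Non-standard residues map through gemmi's tabulation (``X`` if unknown);
    a chain without recognisable amino acids raises.
    """
    letters = []
    numbers = []
    for res in chain.residues:
        info = gemmi.find_tabulated_residue(res.name)
        if res.name in _ONE_LETTER_OVERRIDES:
            one = _ONE_LETTER_OVERRIDES[res.name]
        elif info and info.is_amino_acid():
            one = info.one_letter_code.upper()
            if one not in ALPHABET:
                one = "X"
        else:
            continue
        letters.append(one)
        numbers.append(res.author_number)
    if not letters:
        raise ValueError(f"chain {chain.chain_id} contains no amino acids")
    return "".join(letters), numbers


def chain_numbering(
    model: StructureModel,
    chain_id: str,
    profile: ConsensusProfile,
    params: AlignmentParams = AlignmentParams(),
) -> tuple[NumberingMap, dict[int, int]]:
    """Number a tubulin chain against a family consensus.

    Returns the :class:`NumberingMap` (in modelled-sequence coordinates,
     1-based over modelled residues) and the mapping from author residue
    numbers to those modelled positions, so footprint positions expressed in
    author numbering can be translated to UTN labels.
    """
    chain = model.chain(chain_id)
    if chain.role not in ("alpha", "beta", "gamma"):
        raise ValueError(
            f"chain {chain_id} has role {chain.role!r}; assign a tubulin family role first"
        )
    if chain.role != profile.family:
        raise ValueError(
            f"chain {chain_id} is {chain.role} but profile is {profile.family}"
        )
    seq_str, author_numbers = chain_sequence(chain)
    seq = Sequence(f"{model.structure_id}:{chain_id}", seq_str, chain.role)
    numbering = number_sequence(seq, profile, params)
    author_to_pos = {num: i + 1 for i, num in enumerate(author_numbers)}
    return numbering, author_to_pos
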