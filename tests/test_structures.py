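import numpy as np
import pytest

import gemmi

from _oracles import footprint_all_pairs
from tubnum.numbering import number_sequence
from tubnum.records import FootprintRecord
from tubnum.seqio import Sequence
from tubnum.structures import (
    NoContactResult,
    StructureChain,
    StructureModel,
    StructureResidue,
    chain_numbering,
    chain_sequence,
    footprint,
    load_structure,
)

AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def pdb_atom_line(serial, name, resname, chain, resseq, x, y, z, element, occ=1.0, altloc=" "):
    return (
        f"ATOM  {serial:5d} {name:<4s}{altloc}{resname:<3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2s}"
    )


def minimal_pdb(tmp_path, lines, name="toy.pdb"):
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\nEND\n")
    return p


def single_atom_residue(number, xyz, name="GLY"):
    return StructureResidue(number, name, ("C",), (tuple(xyz),))


def random_model(rng, n_target=200, n_partner=40, box=60.0):
    target = StructureChain(
        "A", "other",
        tuple(
            StructureResidue(
                i + 1, "ALA",
                tuple("C" for _ in range(4)),
                tuple(map(tuple, rng.uniform(0, box, size=(4, 3)))),
            )
            for i in range(n_target)
        ),
    )
    partner = StructureChain(
        "B", "partner",
        tuple(
            StructureResidue(
                j + 1, "GLY",
                tuple("C" for _ in range(3)),
                tuple(map(tuple, rng.uniform(0, box, size=(3, 3)))),
            )
            for j in range(n_partner)
        ),
    )
    return StructureModel("synthetic", (target, partner))


class TestLoading:
    def test_minimal_pdb_two_chains(self, tmp_path):
        lines = [
            pdb_atom_line(1, "CA", "ALA", "A", 1, 0, 0, 0, "C"),
            pdb_atom_line(2, "CA", "GLY", "A", 2, 3, 0, 0, "C"),
            pdb_atom_line(3, "CA", "SER", "B", 1, 10, 0, 0, "C"),
        ]
        model = load_structure(minimal_pdb(tmp_path, lines))
        assert [c.chain_id for c in model.chains] == ["A", "B"]
        assert [r.name for r in model.chain("A").residues] == ["ALA", "GLY"]
        assert model.chain("B").residues[0].author_number == 1

    def test_pdb_and_mmcif_give_identical_models(self, tmp_path):
        lines = [
            pdb_atom_line(1, "CA", "ALA", "A", 5, 1.5, 2.5, 3.5, "C"),
            pdb_atom_line(2, "CB", "ALA", "A", 5, 2.5, 2.5, 3.5, "C"),
            pdb_atom_line(3, "CA", "LYS", "B", 9, 8.0, 1.0, 0.0, "C"),
        ]
        pdb_path = minimal_pdb(tmp_path, lines)
        st = gemmi.read_pdb(str(pdb_path))
        st.setup_entities()
        cif_path = tmp_path / "toy.cif"
        st.make_mmcif_document().write_file(str(cif_path))
        from_pdb = load_structure(pdb_path)
        from_cif = load_structure(cif_path)
        assert from_pdb.chains == from_cif.chains

    def test_hydrogens_and_waters_dropped(self, tmp_path):
        lines = [
            pdb_atom_line(1, "CA", "ALA", "A", 1, 0, 0, 0, "C"),
            pdb_atom_line(2, "H", "ALA", "A", 1, 0.5, 0, 0, "H"),
            pdb_atom_line(3, "O", "HOH", "W", 1, 9, 9, 9, "O"),
        ]
        model = load_structure(minimal_pdb(tmp_path, lines))
        assert len(model.chains) == 1
        assert model.chain("A").residues[0].elements == ("C",)

    def test_highest_occupancy_altloc_kept(self, tmp_path):
        lines = [
            pdb_atom_line(1, "CA", "SER", "A", 1, 0, 0, 0, "C", occ=0.3, altloc="A"),
            pdb_atom_line(2, "CA", "SER", "A", 1, 5, 0, 0, "C", occ=0.7, altloc="B"),
        ]
        model = load_structure(minimal_pdb(tmp_path, lines))
        (res,) = model.chain("A").residues
        assert res.coords == ((5.0, 0.0, 0.0),)


class TestFootprint:
    def test_boundary_is_inclusive_at_cutoff(self):
        target = StructureChain("A", "other", (
            single_atom_residue(1, (0, 0, 0)),
            single_atom_residue(2, (0, 0, 100)),
        ))
        near = StructureModel("t", (target, StructureChain(
            "B", "partner", (single_atom_residue(1, (5.99, 0, 0)),))))
        far = StructureModel("t", (target, StructureChain(
            "B", "partner", (single_atom_residue(1, (6.01, 0, 0)),))))
        assert footprint(near, "A", "B").positions == (1,)
        assert isinstance(footprint(far, "A", "B"), NoContactResult)
        exact = StructureModel("t", (target, StructureChain(
            "B", "partner", (single_atom_residue(1, (6.0, 0, 0)),))))
        assert footprint(exact, "A", "B").positions == (1,)
        assert isinstance(
            footprint(exact, "A", "B", boundary="exclusive"), NoContactResult
        )

    def test_matches_all_pairs_oracle_on_random_models(self):
        """k-d-tree footprints equal a brute-force scan on 25 random structures."""
        for seed in range(25):
            rng = np.random.default_rng(seed)
            model = random_model(rng)
            result = footprint(model, "A", "B", cutoff=6.0)
            got = list(result.positions) if isinstance(result, FootprintRecord) else []
            partner_xyz = model.chain("B").atom_coords()
            expected = footprint_all_pairs(
                [(r.author_number, np.asarray(r.coords)) for r in model.chain("A").residues],
                partner_xyz, 6.0,
            )
            assert got == expected

    def test_cutoff_monotonicity(self, rng):
        model = random_model(rng, n_target=150, n_partner=30)
        sets = []
        for cutoff in (5.0, 6.0, 7.0):
            result = footprint(model, "A", "B", cutoff=cutoff)
            sets.append(set(result.positions) if isinstance(result, FootprintRecord) else set())
        assert sets[0] <= sets[1] <= sets[2]

    def test_symmetry_of_contact_relation(self, rng):
        """If no A residue is within the cutoff of B, no B residue is within it of A."""
        model = random_model(rng, n_target=60, n_partner=25, box=80.0)
        fwd = footprint(model, "A", "B", cutoff=5.0)
        rev = footprint(model, "B", "A", cutoff=5.0)
        assert isinstance(fwd, NoContactResult) == isinstance(rev, NoContactResult)
        if isinstance(fwd, FootprintRecord):
            # every contact pair seen from A has its mirror seen from B
            partner_xyz = model.chain("A").atom_coords()
            expected_rev = footprint_all_pairs(
                [(r.author_number, np.asarray(r.coords)) for r in model.chain("B").residues],
                partner_xyz, 5.0,
            )
            assert list(rev.positions) == expected_rev

    def test_ligand_selection_by_residue_name(self):
        target = StructureChain("A", "alpha", (single_atom_residue(12, (0, 0, 0)),))
        ligand = StructureChain("L", "ligand", (single_atom_residue(1, (3, 0, 0), name="GTP"),))
        model = StructureModel("t", (target, ligand))
        record = footprint(model, "A", "GTP", partner_name="GTP")
        assert record.positions == (12,) and record.family == "alpha"

    def test_empty_partner_selection_rejected(self):
        target = StructureChain("A", "other", (single_atom_residue(1, (0, 0, 0)),))
        model = StructureModel("t", (target,))
        with pytest.raises(ValueError, match="partner"):
            footprint(model, "A", "GTP")

    def test_invalid_cutoff_rejected(self, rng):
        model = random_model(rng, n_target=5, n_partner=2)
        with pytest.raises(ValueError):
            footprint(model, "A", "B", cutoff=0.0)


class TestChainNumbering:
    def _chain_from_sequence(self, residues, start=1, role="alpha", skip=()):
        out = []
        num = start
        for i, aa in enumerate(residues, start=1):
            if i not in skip:
                out.append(StructureResidue(num, AA3[aa], ("C",), ((float(num), 0.0, 0.0),)))
            num += 1
        return StructureChain("A", role, tuple(out))

    def test_consensus_identical_chain_gets_identity_labels(self, alpha_profile):
        seq = alpha_profile.consensus_upper.replace("X", "A")
        chain = self._chain_from_sequence(seq)
        model = StructureModel("toy", (chain,))
        nmap, author_to_pos = chain_numbering(model, "A", alpha_profile)
        assert nmap.deleted_core == frozenset()
        assert author_to_pos[402] == 402
        assert nmap.utn_of(author_to_pos[402]).core_index == 402

    def test_planted_deletion_shifts_downstream_labels(self, alpha_profile, standins):
        """A chain missing two consensus residues numbers downstream +2 relative
        to sequential author numbering."""
        seq = standins["tba1_like"].residues  # consensus minus positions 45-46
        chain = self._chain_from_sequence(seq)
        model = StructureModel("toy", (chain,))
        nmap, author_to_pos = chain_numbering(model, "A", alpha_profile)
        assert nmap.utn_of(author_to_pos[100]).core_index == 102

    def test_fission_yeast_like_chain_author_406_is_utn_402(self, alpha_profile, standins):
        chain = self._chain_from_sequence(standins["nda2_like"].residues)
        model = StructureModel("toy", (chain,))
        nmap, author_to_pos = chain_numbering(model, "A", alpha_profile)
        assert nmap.utn_of(author_to_pos[406]).core_index == 402

    def test_role_mismatch_rejected(self, alpha_profile):
        chain = self._chain_from_sequence("ACDEFGHIKLMNPQRSTVWY", role="partner")
        model = StructureModel("toy", (chain,))
        with pytest.raises(ValueError, match="role"):
            chain_numbering(model, "A", alpha_profile)

    def test_non_protein_chain_rejected(self, alpha_profile):
        chain = StructureChain("L", "alpha", (single_atom_residue(1, (0, 0, 0), name="GTP"),))
        model = StructureModel("toy", (chain,))
        with pytest.raises(ValueError, match="no amino acids"):
            chain_sequence(chain)
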