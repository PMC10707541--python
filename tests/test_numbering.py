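import numpy as np
import pytest

from _oracles import gotoh_global_score
from conftest import random_family_spec
from tubnum import fixtures
from tubnum.consensus import build_profile, profile_from_string
from tubnum.numbering import (
    AlignmentParams,
    DeletedPositionError,
    NumberingMap,
    align_to_consensus,
    assign_family,
    build_numbering,
    equivalent_position,
    number_sequence,
)
from tubnum.seqio import AMINO_ACIDS, Sequence
from tubnum.synth import generate_family
from tubnum.utn import core_label, insertion_label


def random_protein(rng, length):
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutated_copy(rng, seq, rate=0.15, with_indels=True):
    out = []
    for ch in seq:
        r = rng.random()
        if with_indels and r < 0.01:
            continue  # deletion
        if r < rate:
            out.append(str(rng.choice([a for a in AMINO_ACIDS if a != ch])))
        else:
            out.append(ch)
        if with_indels and rng.random() < 0.01:
            out.append(str(rng.choice(list(AMINO_ACIDS))))
    return "".join(out) or "A"


class TestAlignmentScores:
    def test_scores_match_quadratic_reference(self, rng):
        """Global affine-gap scores equal an independent textbook DP on 30 pairs."""
        params = AlignmentParams()
        for k in range(30):
            a = random_protein(rng, int(rng.integers(40, 120)))
            if k % 2:
                b = mutated_copy(rng, a)
            else:
                b = random_protein(rng, int(rng.integers(40, 120)))
            profile = profile_from_string(b)
            aln = align_to_consensus(Sequence("q", a), profile, params)
            assert aln.score == pytest.approx(gotoh_global_score(a, b))

    def test_identical_query_aligns_without_gaps(self, alpha_profile):
        seq = Sequence("self", alpha_profile.consensus_upper.replace("X", "A"))
        aln = align_to_consensus(seq, profile_from_string(seq.residues, "alpha"))
        assert "-" not in aln.query and "-" not in aln.consensus

    def test_single_insertion_opens_one_consensus_gap(self, alpha_profile):
        cons = alpha_profile.consensus_upper.replace("X", "A")
        inserted = next(a for a in AMINO_ACIDS if a not in {cons[39], cons[40]})
        query = cons[:40] + inserted + cons[40:]
        aln = align_to_consensus(Sequence("q", query), profile_from_string(cons, "alpha"))
        assert aln.consensus.count("-") == 1 and aln.query.count("-") == 0
        assert aln.consensus[40] == "-"

    def test_lowercase_and_x_consensus_columns_handled(self):
        profile = profile_from_string("MReVx", "alpha")
        aln = align_to_consensus(Sequence("q", "MREVC"), profile)
        assert "-" not in aln.query  # 'x' column scores 0, still aligned through

    def test_empty_sequence_rejected(self, alpha_profile):
        with pytest.raises(ValueError):
            Sequence("empty", "")


class TestBuildNumbering:
    def test_identity_numbering(self, alpha_profile):
        cons = alpha_profile.consensus_upper.replace("X", "A")
        nmap = number_sequence(Sequence("self", cons, "alpha"), profile_from_string(cons, "alpha"))
        assert nmap.deleted_core == frozenset()
        assert all(lab == core_label(p) for p, _, lab in nmap.entries)

    def test_yeast_like_insertion(self, standins, alpha_profile):
        """+1 insertion after consensus 40: native 41 -> 40i1/1, native 42 -> 41."""
        nmap = number_sequence(standins["tub1_like"], alpha_profile)
        assert nmap.utn_of(41) == insertion_label(40, 1, 1)
        assert nmap.utn_of(42) == core_label(41)
        assert nmap.utn_of(440 + 1) == core_label(440)

    def test_nematode_like_deletion_renumbers_by_plus_two(self, standins, alpha_profile):
        """-2 deletion after position 44: downstream labels = native + 2."""
        nmap = number_sequence(standins["tba1_like"], alpha_profile)
        assert nmap.deleted_core == frozenset({45, 46})
        assert nmap.utn_of(44) == core_label(44)
        for native in (45, 100, 400):
            assert nmap.utn_of(native) == core_label(native + 2)

    def test_tail_labelled_as_insertion_run(self, standins, alpha_profile):
        nmap = number_sequence(standins["tuba1a_like"], alpha_profile)
        assert nmap.tail_start == 441
        assert nmap.utn_of(441) == insertion_label(440, 1, 11)
        assert nmap.utn_of(451) == insertion_label(440, 11, 11)

    def test_n_terminal_overhang_anchored_at_zero(self, alpha_profile):
        cons = alpha_profile.consensus_upper.replace("X", "A")
        lead = "".join(a for a in "WW")
        nmap = number_sequence(Sequence("q", lead + cons, "alpha"),
                               profile_from_string(cons, "alpha"))
        assert nmap.utn_of(1) == insertion_label(0, 1, 2)
        assert nmap.utn_of(3) == core_label(1)


class TestLookups:
    def test_round_trip_on_synthetic_maps(self, rng):
        for _ in range(50):
            spec = random_family_spec(rng)
            _, truth = generate_family(spec)
            nmap = truth[f"syn{int(rng.integers(0, spec.n_sequences)):03d}"]
            for native, _, label in nmap.entries:
                assert nmap.native_of(nmap.utn_of(native)) == native

    def test_deleted_position_error_is_distinct(self, standins, alpha_profile):
        nmap = number_sequence(standins["tba1_like"], alpha_profile)
        with pytest.raises(DeletedPositionError):
            nmap.native_of(core_label(45))
        with pytest.raises(KeyError):
            nmap.native_of(insertion_label(45, 1, 1))
        with pytest.raises(IndexError):
            nmap.utn_of(10_000)

    def test_bijection_enforced(self):
        with pytest.raises(ValueError, match="bijection"):
            NumberingMap("q", "alpha",
                         ((1, "A", core_label(1)), (1, "C", core_label(2))),
                         frozenset(), 0.0)

    def test_tsv_round_trip(self, standins, alpha_profile, tmp_path):
        nmap = number_sequence(standins["nda2_like"], alpha_profile)
        path = tmp_path / "map.tsv"
        nmap.to_tsv(path)
        back = NumberingMap.from_tsv(path)
        assert back.entries == nmap.entries
        assert back.deleted_core == nmap.deleted_core


class TestEquivalentPositions:
    def test_human_to_fission_yeast_like_offsets(self, standins, alpha_profile):
        """Native 402 in the no-indel isotype corresponds to 406 in the +4 one."""
        human = number_sequence(standins["tuba1a_like"], alpha_profile)
        pombe = number_sequence(standins["nda2_like"], alpha_profile)
        assert equivalent_position(human, pombe, 402) == 406
        assert equivalent_position(human, pombe, 174) == 178
        assert equivalent_position(pombe, human, 178) == 174

    def test_identity_between_identical_sequences(self, alpha_profile):
        cons = alpha_profile.consensus_upper.replace("X", "A")
        prof = profile_from_string(cons, "alpha")
        a = number_sequence(Sequence("a", cons, "alpha"), prof)
        b = number_sequence(Sequence("b", cons, "alpha"), prof)
        for pos in (1, 40, 200, len(cons)):
            assert equivalent_position(a, b, pos) == pos

    def test_deletion_yields_none(self, standins, alpha_profile):
        human = number_sequence(standins["tuba1a_like"], alpha_profile)
        worm = number_sequence(standins["tba1_like"], alpha_profile)
        assert equivalent_position(human, worm, 45) is None

    def test_family_mismatch_rejected(self, standins, alpha_profile, all_profiles):
        a = number_sequence(standins["tuba1a_like"], alpha_profile)
        beta_cons = all_profiles["beta"].consensus_upper.replace("X", "A")
        b = number_sequence(Sequence("b", beta_cons, "beta"), all_profiles["beta"])
        with pytest.raises(ValueError, match="family"):
            equivalent_position(a, b, 10)


class TestFamilyAssignment:
    def test_consensus_strings_recover_their_family(self, all_profiles):
        for family, profile in all_profiles.items():
            seq = Sequence("q", profile.consensus_upper.replace("X", "A"))
            assigned, scores = assign_family(seq, all_profiles)
            assert assigned == family
            assert scores[family] == max(scores.values())

    def test_exact_tie_is_unassigned(self):
        profiles = {
            "alpha": profile_from_string("MREVAC", "alpha"),
            "beta": profile_from_string("MREVAC", "beta"),
        }
        assigned, _ = assign_family(Sequence("q", "MREVAC"), profiles)
        assert assigned == "unassigned"

    def test_mutated_copies_recover_family(self, all_profiles, rng):
        """20 copies with 10% random substitutions per family all classify back."""
        for family, profile in all_profiles.items():
            cons = profile.consensus_upper.replace("X", "A")
            for _ in range(20):
                seq = Sequence("m", mutated_copy(rng, cons, rate=0.10, with_indels=False))
                assigned, _ = assign_family(seq, all_profiles)
                assert assigned == family


class TestOffsetLemma:
    def test_gap_free_suffix_offset(self, rng):
        """After a net indel of size d, core label = native - d in the suffix."""
        for _ in range(10):
            spec = random_family_spec(rng)
            msa, truth = generate_family(spec)
            profile = build_profile(msa, max_len=spec.core_length)
            for seq in msa.degapped():
                nmap = number_sequence(seq, profile)
                events = spec.events_for(int(seq.id[3:]))
                if not events:
                    continue
                d = sum(e.length if e.kind == "insertion" else -e.length for e in events)
                last_locus = max(e.position + e.length for e in events)
                for native, _, label in nmap.entries:
                    if not label.is_insertion and label.core_index > last_locus + 1:
                        assert label.core_index == native - d
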