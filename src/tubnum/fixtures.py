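"""Packaged fixtures: printed synthesis tables and synthetic reference families.

Two kinds of fixture live here:

* **Transcribed tables** — the published synthesis tables (clinical variants
  at the dynein and doublecortin interfaces, PTM-ablating tubulinopathy
  mutations, breast-cancer isotype mutation sets), the printed interface
  footprint lists, the PTM-site annotations backing them, and the accession
  lists of the sequences behind each family consensus.  These ship as TSV
  files guarded by SHA-256 checksums.

* **Synthetic reference families** — deterministic tubulin-like families
  (90 α-like, 90 β-like, 21 γ-like rows) built by :mod:`tubnum.synth`, from
  which the packaged consensus profiles are derived.  They are *synthetic*:
  offline stand-ins with the size, conservation level, and indel structure
  of the real families, not the published consensus sequences.  The same is
  true of :func:`standin_sequences`, which provides synthetic analogues of
  the classic numbering exceptions (a budding-yeast-like +1 insertion after
  position 40, a nematode-like 2-residue deletion after position 44, a
  fission-yeast-like +4 insertion, and a human-like exact match with an
  11-residue carboxy-terminal tail).
"""

from __future__ import annotations

import hashlib
import json
from functools import lru_cache
from importlib import resources
from pathlib import Path

from .consensus import ConsensusProfile, build_profile
from .records import RecordTable, read_table
from .seqio import MSA, Sequence
from .synth import IndelEvent, SyntheticFamilySpec, generate_family

__all__ = [
    "FIXTURE_NAMES",
    "FAMILY_SPECS",
    "IntegrityError",
    "fixture_path",
    "load_fixture",
    "family_msa",
    "consensus_profile",
    "standin_sequences",
]


class IntegrityError(RuntimeError):
    """A packaged fixture's checksum does not match the manifest."""


_TABLE_FIXTURES = {
    "table1": ("table1.tsv", "mutation"),
    "table2": ("table2.tsv", "mutation"),
    "table3": ("table3.tsv", "mutation"),
    "table4": ("table4.tsv", "mutation"),
    "ptm_sites_alpha": ("ptm_sites_alpha.tsv", "ptm"),
    "ptm_sites_beta": ("ptm_sites_beta.tsv", "ptm"),
    "dynein_footprint": ("dynein_footprint.tsv", "footprint"),
    "doublecortin_footprint": ("doublecortin_footprint.tsv", "footprint"),
}

FIXTURE_NAMES = tuple(_TABLE_FIXTURES) + (
    "consensus_alpha",
    "consensus_beta",
    "consensus_gamma",
    "accession_lists",
)

#: Synthetic reference families: sizes follow the real consensus inputs
#: (90 α, 90 β, 21 γ sequences); core lengths are tubulin-like and exceed
#: 440 so profile truncation is active.  Each family plants the documented
#: kinds of rare indels (single-residue insertion, short deletion).
FAMILY_SPECS = {
    "alpha": SyntheticFamilySpec(
        n_sequences=90,
        core_length=451,
        substitution_rate=0.08,
        indel_events=(
            IndelEvent(3, 40, 1, "insertion"),   # yeast-like +1 after 40
            IndelEvent(7, 45, 2, "deletion"),    # nematode-like -2 after 44
            IndelEvent(11, 38, 4, "insertion"),  # fission-yeast-like +4
        ),
        seed=101,
        family="alpha",
    ),
    "beta": SyntheticFamilySpec(
        n_sequences=90,
        core_length=445,
        substitution_rate=0.08,
        indel_events=(
            IndelEvent(5, 56, 1, "insertion"),
            IndelEvent(9, 361, 3, "deletion"),
        ),
        seed=102,
        family="beta",
    ),
    "gamma": SyntheticFamilySpec(
        n_sequences=21,
        core_length=444,
        substitution_rate=0.05,
        indel_events=(
            IndelEvent(2, 120, 2, "insertion"),
        ),
        seed=103,
        family="gamma",
    ),
}


def fixture_path(filename: str) -> Path:
    return Path(resources.files("tubnum").joinpath("data", filename))


@lru_cache(maxsize=1)
def _checksums() -> dict[str, str]:
    return json.loads(fixture_path("checksums.json").read_text())


def _verified_path(filename: str) -> Path:
    path = fixture_path(filename)
    expected = _checksums().get(filename)
    if expected is None:
        raise IntegrityError(f"{filename} missing from checksum manifest")
    actual = hashlib.sha256(path.read_bytes()).hexdigest()
    if actual != expected:
        raise IntegrityError(
            f"{filename}: checksum mismatch (expected {expected[:12]}…, got {actual[:12]}…)"
        )
    return path


@lru_cache(maxsize=None)
def family_msa(family: str) -> MSA:
    """The synthetic reference family alignment for alpha|beta|gamma."""
    msa, _ = generate_family(FAMILY_SPECS[family])
    return msa


@lru_cache(maxsize=None)
def consensus_profile(family: str) -> ConsensusProfile:
    """Consensus profile of a synthetic reference family (length 440)."""
    return build_profile(family_msa(family), family=family)


def _accession_lists() -> dict[str, list[dict[str, str]]]:
    import csv

    path = _verified_path("accessions.tsv")
    out: dict[str, list[dict[str, str]]] = {"alpha": [], "beta": [], "gamma": []}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["family"]].append(
                {"accession": row["accession"], "flag": row["flag"]}
            )
    return out


def load_fixture(name: str):
    """Load a packaged fixture by name.

    Table fixtures return a :class:`~tubnum.records.RecordTable`;
    ``consensus_<family>`` returns a :class:`~tubnum.consensus.ConsensusProfile`
    (synthetic, regenerated deterministically); ``accession_lists`` returns
    the per-family accession lists with per-entry flags.
    """
    if name in _TABLE_FIXTURES:
        filename, kind = _TABLE_FIXTURES[name]
        return read_table(_verified_path(filename), kind)
    if name.startswith("consensus_"):
        family = name.removeprefix("consensus_")
        if family in FAMILY_SPECS:
            return consensus_profile(family)
    if name == "accession_lists":
        return _accession_lists()
    raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURE_NAMES)}")


def _pick_letter(forbidden: set[str], preferred: str = "S") -> str:
    if preferred not in forbidden:
        return preferred
    for aa in "SGAPQNDEKRHTVLIMFWYC":
        if aa not in forbidden:
            return aa
    raise AssertionError("unreachable: 20 letters cannot all be forbidden")


@lru_cache(maxsize=1)
def standin_sequences() -> dict[str, Sequence]:
    """Synthetic analogues of the documented α-tubulin numbering exceptions.

    All are derived from the synthetic α consensus:

    * ``tub1_like``  — one residue inserted after consensus position 40
      (the budding-yeast α1-tubulin pattern: native 41 becomes 40i1/1 and
      native 42 renumbers to 41);
    * ``tba1_like``  — consensus positions 45-46 deleted (the nematode
      α-tubulin-2 pattern: natives after 44 renumber by +2);
    * ``nda2_like``  — four residues inserted after position 38 (the
      fission-yeast pattern: native 178 maps to 174 and 406 to 402);
    * ``tuba1a_like`` — identical to the consensus core with an 11-residue
      carboxy-terminal tail (the human α1A pattern: numbering unaltered,
      tail labelled as a 440-anchored insertion run).
    """
    cons = consensus_profile("alpha").consensus_upper.replace("X", "A")
    c = list(cons)

    ins1 = _pick_letter({c[39], c[40]})
    tub1 = "".join(c[:40]) + ins1 + "".join(c[40:])

    tba1 = "".join(c[:44]) + "".join(c[46:])

    run4 = []
    forbidden = {c[37], c[38]}
    for offset in range(4):
        run4.append(_pick_letter(forbidden | set(run4), "GSNQ"[offset]))
    nda2 = "".join(c[:38]) + "".join(run4) + "".join(c[38:])

    tail = "".join(
        _pick_letter({c[-1]}, preferred) for preferred in "GEEEGEEYDEA"
    )
    tuba1a = cons + tail

    return {
        "tub1_like": Sequence("TUB1_like_synthetic", tub1, "alpha"),
        "tba1_like": Sequence("TBA1_like_synthetic", tba1, "alpha"),
        "nda2_like": Sequence("NDA2_like_synthetic", nda2, "alpha"),
        "tuba1a_like": Sequence("TUBA1A_like_synthetic", tuba1a, "alpha"),
    }
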