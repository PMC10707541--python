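# tubnum

Universal tubulin numbering (UTN) and cross-referencing for the tubulin
superfamily.

Tubulins (α, β, γ) are extraordinarily conserved, yet individual isotypes
and species carry rare short insertions and deletions that shift residue
numbering — the budding-yeast α1-tubulin insertion near position 40, the
two-residue deletion in the *C. elegans* α-tubulin H1′–S2 loop, the
four-residue offset that makes vertebrate α-tubulin R402 the equivalent of
R406 in fission yeast.  This makes it hard to relate missense mutations,
post-translational modification (PTM) sites, and structural interface
residues across organisms.  `tubnum` solves this for researchers who work
with tubulin variants (tubulinopathies, drug resistance, model-organism
genetics) by indexing every sequence against a per-family consensus:

* **Consensus profiles** — built from a family alignment by removing
  uncommon insertion columns (occupancy < 0.5), calling the per-column
  plurality residue with a confidence case (UPPERCASE ≥ 0.5, lowercase
  ≥ 0.25, `x` below), and truncating at 440 residues to exclude the
  heterogeneous carboxy-terminal tail.  Numeric conservation profiles and
  Lesk colour classes come along for free.
* **Numbering** — any tubulin is globally aligned to its family consensus
  (BLOSUM62 scores, affine gaps 10/0.5).  A residue aligned to consensus
  column *i* is position *i*; an inserted run is labelled
  `<anchor>i<ordinal>/<run_length>` (a single residue inserted after
  position 40 is `40i1/1`) without shifting downstream numbering; deletions
  renumber the remainder onto consensus coordinates.  The map is a
  bijection, so positions translate between any two tubulins of a family.
* **Footprints** — residues with any heavy atom within 6 Å of a bound
  ligand or partner chain, extracted from PDB/mmCIF structures and
  expressible in UTN coordinates.
* **Cross-referencing** — joins of UTN-indexed mutation, PTM-site, and
  footprint tables: which clinical variants sit in a motor-protein
  footprint, which substitutions ablate documented modification sites,
  and per-position summaries over the 440 consensus columns.

The published synthesis tables (clinical variants at the dynein and
doublecortin interfaces, PTM-ablating tubulinopathy mutations, breast-cancer
β-isotype mutation sets, and the printed interface footprint lists) ship as
checksummed TSV fixtures.  The packaged consensus profiles and reference
sequences are *synthetic* — deterministic tubulin-like families with the
documented sizes (90 α, 90 β, 21 γ) and indel structure, generated by
`tubnum.synth` — see `docs/methods.md` for what that does and does not
validate.

## Worked example

Number a yeast-like α-tubulin (one extra residue after consensus position
40) against the α consensus:

```sh
python - <<'EOF'
from tubnum import fixtures
from tubnum.seqio import write_fasta
fixtures.consensus_profile("alpha").to_json("alpha.json")
write_fasta([fixtures.standin_sequences()["tub1_like"]], "tub1_like.fa")
EOF
tubnum number --fasta tub1_like.fa --profile alpha.json --out map.tsv
```

The map shows the insertion label and the downstream renumbering — native
position 41 is an insertion, native 42 *is* universal position 41:

```
native_pos	residue	utn_label	note
40	H	40	core
41	S	40i1/1	insertion
42	P	41	core
```

Join the packaged clinical-variant table against the printed dynein
footprint:

```sh
tubnum crossref --mutations table1.tsv --footprints dynein_footprint.tsv \
    --report footprint --out report.tsv
```

```
family	utn_position	utn_label	isotype	species	substitution	phenotype	partner
alpha	110	110	α-1A	H. sapiens	T110A	Tubulinopathies	dynein
alpha	113	113	α-1A	H. sapiens	E113K	Tubulinopathies	dynein
```

All 42 printed variant rows fall inside the footprint; they cover 14
distinct (family, position) sites — the α402 hotspot plus 13 others.

In Python the same pipeline is three calls:

```python
from tubnum import fixtures, index_by_utn, mutations_in_footprint

muts = index_by_utn(fixtures.load_fixture("table1"))
report = mutations_in_footprint(muts, fixtures.load_fixture("dynein_footprint"))
print(len(report.distinct_sites() - {("alpha", 402)}))   # -> 13
```

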