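# Methods

## The universal numbering model

Each tubulin family (α, β, γ) gets a consensus coordinate system derived
from a family multiple sequence alignment:

1. **Insertion-column removal.** An alignment column occupied by fewer than
   a fraction `occupancy_threshold` (default 0.5) of the rows is treated as
   an uncommon insertion and removed.  The surviving columns define the
   family's core coordinates.  The default is deliberately permissive: a
   tubulin-family insertion present in one or a few sequences (occupancy
   ~0.01–0.1) is removed at any sensible threshold, while a column present
   in most members is structural signal and must be kept.
2. **Consensus calling.** Per kept column, the plurality residue among
   non-gap rows is emitted UPPERCASE if its frequency ≥ `upper_threshold`
   (default 0.5), lowercase between `lower_threshold` (default 0.25) and
   the upper threshold, and `x` when no residue reaches the lower
   threshold.  Frequencies are computed over non-gap rows only and ties are
   broken alphabetically so calls are deterministic.  The thresholds are
   exposed because consensus tools differ in their defaults; for tubulins —
   where most columns exceed 90 % identity — the calls are insensitive to
   the exact values.
3. **Truncation at 440.** The carboxy-terminal tail (CTT) is heterogeneous
   in length and sequence across isotypes, so profiles are cut at 440
   columns and the CTT is excluded from position-level indexing.

A query sequence is then numbered by end-to-end global alignment to the
consensus string.  Scoring uses BLOSUM62 with affine gap penalties
(open 10, extend 0.5; a gap of length L costs `open + (L−1)·extend`), end
gaps penalised.  Lowercase consensus letters score as their uppercase
residue; `x` columns (and the unknown residue `X`) score 0 against
everything, i.e. they neither attract nor repel the alignment.  Tubulin
families are conserved enough (well above 40 % identity to their consensus)
that the numbering is robust to the choice of matrix; the alignment layer
is Biopython's `PairwiseAligner`, and the test suite checks its scores
against an independent textbook affine-gap dynamic program.  Among
co-optimal alignments the aligner's canonical first traceback is used, so
maps are reproducible for fixed inputs and parameters.

The alignment induces the numbering map:

* query residue aligned to consensus column *i* → core label *i*;
* query residues opposite consensus gaps → an insertion run
  `<anchor>i<ordinal>/<run_length>` anchored at the last preceding core
  position (anchor 0 for an N-terminal overhang).  Insertions never shift
  downstream numbering.  The notation encodes both the size of the insert
  and the position of each residue within it; a three-residue insert after
  position 112 reads `112i1/3`, `112i2/3`, `112i3/3`.
* consensus columns opposite query gaps → recorded as deleted core
  positions; the rest of the query thereby renumbers onto consensus
  coordinates (a two-residue deletion shifts downstream labels by +2);
* query residues past the final consensus column (the CTT) → an insertion
  run anchored at the last core position, mirroring the CTT exclusion.

The map is a bijection between native positions and labels.  Deleted core
positions have *no* label; looking one up raises a dedicated
"no residue at this position" error, distinct from out-of-range.  Position
translation between two sequences of the same family goes native → label →
native; insertion labels translate only on exact (anchor, ordinal) match.

## PTM model and the ablation rule

Each modification type carries its set of modifiable residues
(phosphorylation S/T/Y, acetylation K, methylation H/K/R, nitrosylation and
palmitoylation C, glutamylation and glycylation E, malonylation,
succinylation, SUMOylation and ubiquitination K, O-linked glycosylation
S/T).  Citrullination is fixed to R by chemistry; MARylation, for which no
single canonical acceptor list exists, uses the common acceptor set
E/D/R/S/K.  Detyrosination/retyrosination and CTT polyglutamylation/
polyglycylation are recognised type names but are never attached to UTN
positions, since the CTT lies outside the 440-column core.

The default ablation rule is **site-specific**: any missense change at a
documented modification site ablates all of the site's modification types,
including chemically conservative changes (T→S at a phospho-site, K→R at an
acetylation site).  The rationale is empirical: the curated synthesis
tables count exactly such substitutions as losses, reflecting that the
documented site — the residue the modifying enzyme was shown or predicted
to act on — is gone even when the replacement is modifiable in principle.
A **chemistry-preserving** variant (only changes leaving the modifiable
residue class count) is available behind a flag for sensitivity analysis.
Truncations (target residue `X`) and incomplete substitution tokens never
enter ablation calls.  Gains of a modifiable residue (e.g. S→C creating a
palmitoylatable cysteine) are reported as informational notes only, never
as losses.

## Footprints

A footprint is the set of target-chain residues with at least one heavy
atom within a distance cutoff (default 6.0 Å, boundary inclusive) of any
heavy atom of a partner selection (a chain id, or a ligand residue name
such as GTP).  Selection is by-residue — one contact atom pulls in the
whole residue — because published footprint lists are residue lists.
Hydrogens are dropped, waters excluded, the highest-occupancy alternative
conformation kept, and only the first model of an ensemble used.  Author
residue numbering is reported, since published footprints use biological
numbering; `chain_numbering` translates author numbers to UTN labels via
the numbering module.  The neighbour search uses a k-d tree; tests verify
exact agreement with an all-pairs distance scan and monotonicity in the
cutoff (5 Å ⊆ 6 Å ⊆ 7 Å).

## Cross-referencing

Joins are on (family, core UTN position); insertion labels join only on
exact equality.  Distinct *sites* are unique (family, position) pairs
regardless of isotype — β162 and β163 variants in different isotypes are
separate sites, while multiple substitutions of the same arginine collapse
to one.  Records from different sources are never merged; every report row
carries the provenance strings of all records it joins.  Records whose
position is deleted in their isotype are flagged, not silently dropped.
Entry-level ablation summaries (`ablations_by_entry`) operate on table rows
that may carry several substitutions (one tumour sample, one isotype) and
report the union of ablated types per entry; positions in those tables are
taken as already UTN-aligned, which holds for the packaged human β-isotype
entries (no indels relative to the consensus).

## Synthetic data: what it emulates and what it does not

The generator (`tubnum.synth`) produces families of highly similar
sequences of a fixed core length with planted short indels, plus the exact
numbering map each planting implies, constructed directly rather than by
alignment.  Residues are uniform over the 20 amino acids; point
substitutions are applied per-residue at a configurable rate.  To keep the
planted ground truth the unique optimum of the alignment problem, a window
around every indel is shielded from substitutions in all rows, inserted
letters are chosen to differ from the ancestor content of the window an
optimal alignment could slide them into, and deletions never remove a
residue whose flanks would make a shifted deletion score-identical.  The
packaged reference families use the study sizes (90 α-like, 90 β-like,
21 γ-like sequences; substitution rates 0.08/0.08/0.05, i.e. ~85–95 %
pairwise identity, the high-conservation regime typical of within-family
tubulin comparisons) and plant the documented kinds of exceptions: a +1
insertion after position 40, a 2-residue deletion after 44, a +4 insertion
in the N-terminal third.

What passing tests on synthetic families shows: the numbering pipeline
recovers planted indels exactly, the insertion/deletion labelling rules are
implemented correctly, and position translation is a bijection.  What it
does not show: agreement with the *published* consensus strings (the real
sequence set is not bundled), behaviour on families with phylogenetic
rate structure rather than star-tree noise, or numbering of genuinely
ambiguous indels in low-complexity regions, where co-optimal alignments
exist and the reported map is the aligner's canonical choice among them.
The packaged "stand-in" sequences (`fixtures.standin_sequences`) are
synthetic analogues of the documented per-species numbering exceptions,
not the UniProt records themselves; tests against them validate the rules,
not the transcription of any particular database entry.

## Numerical and design choices

* Coordinates are 1-based and inclusive throughout; deletions produce no
  label, only bookkeeping.
* Plurality ties in consensus calling break alphabetically; family
  assignment returns "unassigned" when the top two family scores tie
  (margin configurable).
* Sequence weighting in consensus construction is not implemented; all
  rows weigh 1.
* Ambiguity codes B/Z/U/O are mapped to X (scores 0) with a logged
  warning; gap characters `-` and `.` are both accepted and normalised.
* Substitution tokens parse as `<from><pos><to>`; `X` as target denotes a
  truncation (kept as a record, excluded from ablation); a bare
  `<from><pos>` token — one occurs verbatim in a published table — is kept
  as an incomplete record.
* The synthesis tables are packaged exactly as printed, including
  non-standard provenance prefixes; a SHA-256 manifest guards the
  transcription.
* The per-family consensus profiles packaged here are synthetic stand-ins
  (see above).  Users with access to a published consensus string can load
  it directly via `consensus.profile_from_string` and number against it;
  every downstream step is consensus-agnostic.

## Problem sizes

The test suite runs entirely on synthetic data at desk scale: families of
4–9 sequences of length 80–160 for property checks (50 families in the
acceptance suite), 30 alignment-score oracle pairs of length 40–120, 25
random 200-residue structures for footprint oracles, and the three packaged
90/90/21-sequence reference families.  The full suite completes in well
under a minute.

## Known limitations

* δ-, ε- and ζ-tubulins are out of scope: their large, variable insertions
  (12–32+ residues) make a family consensus unreliable; pairwise alignment
  is the recommended route for those families.
* The ablation rule is positional, not mechanistic: it does not model
  motif context, enzyme specificity, or compensatory sites.
* Footprints are geometric (distance cutoff on heavy atoms); no energetic
  or interface-area criterion is applied.
* CTT modifications (polyglutamylation, polyglycylation, detyrosination)
  are represented as types but cannot be indexed to UTN positions by
  construction.
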