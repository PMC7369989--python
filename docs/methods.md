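# Methods

## Scope and model

cypminer implements the classical motif-plus-identity workflow for
annotating bacterial cytochrome P450s and relating them to secondary
metabolism. Its assumptions are those of the underlying survey practice:

* A candidate set of hit proteins is given (in practice from an InterPro or
  HMM search); cypminer does not perform candidate discovery. Triage then
  rests entirely on the two conserved signatures, ExxR (K helix) and CxG
  (heme loop), and on length.
* Family and subfamily membership is decided purely by percent identity to
  the nearest named homolog (> 40% family, > 55% subfamily, strict
  inequalities). Phylogeny-aware reassignment is out of scope.
* BGC detection is external: cluster coordinates and type labels arrive as
  an antiSMASH-style table and are taken at face value.

## Triage rules

Motifs are matched with exact anchors (E/R, C/G) and unconstrained wildcard
positions (any residue, including X), everywhere in the sequence —
overlapping hits are all reported. The category logic is:

| ExxR | CxG | length < `fragment_max_len` | category |
|------|-----|------------------------------|----------|
| yes  | yes | —                            | COMPLETE |
| one of the two | | —                      | PSEUDO   |
| no   | no  | yes                          | FRAGMENT |
| no   | no  | no                           | NON_CANDIDATE |

"Short" is not defined by survey practice; `fragment_max_len` defaults to
300 residues (a typical bacterial P450 is ≈ 400), splitting truncated hits
from unrelated full-length proteins conservatively. "One of these motifs"
is read as exactly one — both motifs always means COMPLETE. Motif order is
not required. Position restriction (e.g. requiring CxG in the C-terminal
region) is deliberately not applied by default.

## Alignment and identity

Assignment identity is computed from an optimal **global** alignment
(affine gaps, BLOSUM62, open 10 / extend 1, first gap residue pays the
opening penalty) with gap columns in the denominator:
`identity = 100 × identical columns / columns`. Survey practice typically
uses BLAST local identity; global identity over the full sequence is
stricter and fully deterministic, which this package prioritises. A local
(Smith–Waterman) identity mode is available on every scoring surface
(`mode="local"`) for sensitivity analysis.

Numerical choices:

* The Gotoh dynamic program is numba-compiled; scores are float64.
* Traceback ties are resolved diagonal → up → left at the
  predecessor-state level, making alignments bit-reproducible; the test
  suite checks the whole alignment (not just the score) against exhaustive
  enumeration on short pairs, and the score against an independent
  implementation on longer pairs.
* Residues outside the substitution matrix's alphabet (J, O, U for
  BLOSUM62) score as 'X'.
* Ties among equally identical references go to the lexicographically
  smallest reference name.

Exactly-at-threshold identities demote: 55.0% is a family-level call,
40.0% founds a new family.

## Placeholder naming

Software cannot mint CYP numbers, so novel queries get `NEWF001`, ... in
order of first appearance over queries sorted by (species, protein id).
Novel queries sharing > 40% identity are merged into one placeholder family
by single-linkage; within such a family, > 55% links merge subfamilies
(`NEWF001-newSF1`). Family-level queries get per-family placeholders
(`CYP105-newSF1`) grouped the same way. Single-linkage is a deliberate
choice where practice is silent on how multiple novel queries coalesce; it
is order-independent and conservative (any >-threshold path merges).

## BGC membership and tabulation

Intervals are 1-based inclusive throughout (GFF3 convention). Membership
defaults to any ≥ 1-base overlap on the same contig of the same species,
strand ignored; full containment is available (`overlap="contained"`). A
P450 inside two overlapping clusters produces two memberships, but counts
once toward the percentage of P450s inside BGCs. Hybrid clusters contribute
one count per type label in linkage tables and type tallies, preserving
per-type totals without inventing a primary-type rule. Gene-to-protein
matching requires `gene_id == protein_id` (identifier schemes across genome
portals differ; the one-to-one convention is declared rather than guessed).

## Cohort statistics

Averages are integer-rounded **half away from zero**; percentages are
**truncated**. This is the only combination consistent with the published
comparative roll-up this module emulates (26.90 → 27, 30.95 → 31,
22.54 → 22, 29.73 → 30, 11.43 → 11, 3.96 → 4); the cyanobacteria percentage
cell printed there (7.92 shown as 8) contradicts truncation and is treated
as the source table's inconsistency — cypminer computes 7. Modal counts
break ties toward the smaller value. The presence matrix encodes presence
as 3 and absence as −3, the heat-map tool convention; image rendering and
clustering of the matrix are out of scope. BGC totals, averages and the
in-BGC percentage always use the same species subset (those with cluster
data) for numerator and denominator; both totals are exposed.

The bundled per-species table (203 *Streptomyces* proteomes) sums to 5460
P450s and yields mode 19, minimum 10, maximum 30 families and 58
subfamilies per species. Its largest per-species count is 68; prose
accounts of the same survey say 69 — cypminer reports what its input table
contains.

## Synthetic cohorts

The generator emulates the survey's input shapes, not P450 biology:
sequences are uniform random 20-letter strings with motifs planted at
canonical relative positions (ExxR at ~68% of length, CxG at ~85%), not
HMM-sampled P450s. Passing tests therefore demonstrate the correctness of
triage logic, identity arithmetic, threshold handling, interval logic and
roll-up arithmetic — not classifier performance on real proteomes, where
homology is not a clean identity dial.

Default study conditions (one `SimSpec`): 5 species; per species 2
subfamily-level P450s (planted identity 72–83%), 1 family-level (46–49%),
1 novel (< 37% to every reference), 1 pseudo-P450, 1 fragment
(80–180 aa), 1 non-candidate; a reference database of 4 families × 2
subfamilies (420 aa; family seeds mutually < 35%, subfamily
representatives at 46–49% of their seed); 20% of P450 genes inside
clusters (the in-BGC proportion observed for actinomycetes), plus 2
P450-free decoy clusters per species; genes laid 2 kb apart on one contig
so cluster windows (gene ± 300 bp) never capture a neighbour. These sizes
keep a full end-to-end run in seconds while exercising every code path;
they are the package's declared conditions, not tuned values.

Identity targeting is accept/reject: substitute `k ≈ L(1 − t/100)`
non-anchor positions, re-measure with the package's own aligner, adjust
`k`, accept within ±2 points. Closed-form substitution counts are not used
because gapped global identity is not a simple function of the substitution
count. Planted targets avoid the bands [37, 43] and [52, 58] so targeting
noise can never flip an assignment; a `threshold_stress` flag generates
in-band cases for boundary testing. The generator verifies (and fails
loudly rather than silently accepting) that family seeds are mutually
distant, that novel P450s are mutually below the family band, and that
family-level mutants of one seed are mutually below the subfamily band —
making the truth summary a pure counting consequence of the design.
Everything derives from one `numpy` `SeedSequence`, spawned per stage and
species: identical specs give byte-identical bundles.

## Known limitations

* Global-alignment identity is not BLAST identity; absolute identity values
  differ from survey practice near the thresholds (the switchable local
  mode exists to probe this).
* Candidate discovery, phylogenetics, heat-map rendering, cluster
  detection and the separation of P450-derived glycosyltransferase
  activator proteins (no published rule exists) are out of scope.
* Synthetic sequences are compositionally uniform; conclusions about
  recovery rates do not transfer to real proteomes.
* Placeholder families are package-local names, not nomenclature
  assignments.
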