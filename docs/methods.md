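# Methods

## The module grammar

Cysteine-rich eggshell-membrane proteins (CREMPs) are built from tandem
modules of four cysteines with fixed spacing plus a C-terminal tail:

- **a module**: C-X4-C-X5-C-X8-C-X6 — 27 residues.
- **b module**: C-X4-C-X5-C-X8-C-X11 — 32 residues.

X is any residue except cysteine; cysteines are hard anchors. One a
followed by one b gives the 59-residue repeat; an a-b-a-b concatenation
gives the 118-residue fragment with 16 cysteines (8 disulfides when fully
oxidized). Beyond the anchors, a catalogue of diagnostic residues is
conserved: D3, K8, G9, G17 and P19 in both types; P7 and P26 only in a;
K25 only in b.

Module positions are numbered 1-based from the first cysteine. The
sources that describe the conserved positions never state the numbering
origin explicitly; position 1 = first cysteine is the only origin under
which all eight catalogued residues fall between the correct anchors
(C at 1, 6, 12, 21), so it is adopted everywhere and flagged here.

Grammars are configuration (`cremp/data/cremp_grammar.yaml`): label,
internal gaps, tail, per-gap tolerance (default 1, covering the two
documented single-residue spacing deviations), and a maximum tail insert
(default 64, covering the longest documented insert of 59 residues).
Looser grammars — e.g. the slime-mold spore-coat C-X4-C-X5-C-X6..10-C
spacing — can be expressed with a tolerant third gap.

## Detection

No detection algorithm accompanies the repeat formula, so the scanner is
designed around the grammar's structure:

1. **Candidates.** Because spacers are cysteine-free, a module's four
   anchors are consecutive entries in the sequence's cysteine list. Every
   window of four consecutive cysteines is tested against every spec;
   gaps must match within tolerance (deviations flagged `gap_shrunk` /
   `gap_grown`). The tail is delimited by the next cysteine: its length
   must lie in `[tail, tail + max_tail_insert]`, the excess recorded as a
   `tail_insert`. With no downstream cysteine the tail is capped at
   canonical length, and a candidate whose canonical tail would run past
   the sequence end is rejected — inserts are only observable when
   bounded by the next module's anchor, and unbounded tails would
   otherwise create spurious readings at the sequence edge.
2. **Chaining.** Weighted-interval-scheduling dynamic programming selects
   a non-overlapping subset maximizing, lexicographically: residues
   covered, module count, fewest deviations; remaining ties resolve
   toward smaller start, then spec label. Adjacent selected modules
   (gap ≤ `max_gap_between_modules`, default 0 — observed repeats are
   contiguous) form one `RepeatRegion`.

One window can satisfy several specs (an exact b reading is also an a
reading with a 5-residue insert); both candidates are kept and the
deviation tie-break settles the canonical case in favour of b.

Two consequences worth knowing:

- A tail-insert hit cannot be reproduced by rescanning its excised
  subsequence alone: the insert's delimiting cysteine belongs to the next
  module, so the rescan caps the tail at canonical length. The
  rescan-identity property therefore holds for non-insert hits only.
- An a module followed by ≥5 cysteine-free non-repeat residues is locally
  indistinguishable from a b module at chaining time (the b reading
  covers more residues); only the diagnostic residues, applied later by
  the classifier, could tell them apart. Equivalently, an a module with a
  tail insert of exactly 5 is structurally identical to a b module.

## Classification

A rule cascade, deterministic by construction:

1. canonical gaps and tail exactly 6 → **a**; exactly 11 → **b**;
2. otherwise diagnostic residues vote (P7, P26 for a; K25 for b); the
   majority gives **a_variant**/**b_variant**;
3. no or tied votes: tail proximity (net of the insert) to 6 vs 11;
   exact equidistance would give **unknown** (unreachable with the a/b
   tails, but defined for custom grammars).

Diagnostic positions are read in the canonical frame shifted by the
cumulative gap offset, i.e. anchored to the preceding cysteine, so a
shrunk first gap moves every downstream diagnostic left by one. Evidence
lists only the diagnostics consistent with the assigned label, plus a
`conflicts` flag when both sides had support. In architecture strings,
a_variant/b_variant render as their type letter ("a"/"b"); only
unclassified or unknown modules render "v".

## Conservation profiles

Same-type modules align without gaps once gap-deviant modules are
excluded (they would need a true alignment, which is out of scope);
insert-bearing modules contribute their canonical-length prefix. For
cross-type stacks every b row is trimmed by exactly 5 C-terminal residues
to the 27-residue a length — the same equal-length device used in the
original a/b comparison. Information content is the WebLogo protein
convention, log2(20) − H in bits, with no small-sample correction (stack
sizes are small and applying one would be a modeling choice, not a
faithfulness improvement; both frequencies and bits appear in the TSV
output). X is carried as a 21st symbol: it contributes its own entropy
term and can never look conserved. Consensus and conserved-position
tie-breaks are lexicographic — arbitrary but deterministic.

## Composition distance

Compositions are 17-component percentage vectors: the 20 standard
residues minus tryptophan, with D+N and E+Q pooled — the form in which
acid-hydrolysis literature reports membrane compositions (W is destroyed,
amides deamidated). Hydroxylysine/hydroxyproline in literature reference
tables fold into K/P at config load; X carries no information and is
excluded like W. Distances are plain Euclidean on percentages. The
shipped reference file pins only the two membrane values available in
accessible text (Gly 9.5%, Cys 10.1%) as an explicitly partial entry;
full collagen/keratin/elastin vectors are user-supplied, so the ranking
procedure is reproducible in form without inventing numbers. The
canonical (a-b)n repeat is 8/59 ≈ 13.6% cysteine — qualitatively matching
the high measured cysteine content of the membrane, though the canonical
alanine filler means exact agreement is not expected.

## Segregation analysis

The historical a/b-segregation observation used a multiple aligner's
guide tree; re-running an external aligner adds nothing testable, so the
claim is recast as: p-distance matrix over a cross-type stack → UPGMA →
purity of the two root-level clusters (fraction of leaves matching their
subtree's majority type). p-distance counts X as mismatching everything,
including X. UPGMA merges the closest pair at height d/2 with
size-weighted average updates; ties break toward the lexicographically
smallest representative-label pair. Needleman–Wunsch identity
(match 1 / mismatch 0 / gap −1, traceback diagonal → up → left) is
provided for direct repeat comparisons; published identity percentages
for specific repeat pairs depend on an unstated alignment scoring and are
not reproduction targets. UPGMA heights are cross-checked against scipy
average linkage, and alignment scores against Biopython's
PairwiseAligner, in the test suite.

## Synthetic data

`simulate_protein` builds each planned module from its canonical
sequence, applies scheduled gap edits (rebuilt per segment so diagnostics
stay anchored to their cysteines) and tail inserts, then substitutes
unprotected positions at the given rate. Defaults encode the documented
conditions: protected anchors and diagnostics (substitutions never
introduce C while anchors are protected), cysteine-free flanks uniform
over the 19 non-C residues, and an insert alphabet of 45% A / 45% P /
10% spread over the other non-C residues — a stylized encoding of the
proline/alanine-rich inserts with their AP runs. The generator emulates
module grammar, point substitutions, the two documented spacing-deviation
classes and progressive inserts; it does **not** emulate duplication
histories, general indels, correlated (phylogenetic) substitutions
within a type, or real inter-module flank composition. Passing tests
therefore demonstrate correctness of detection and bookkeeping under the
stated noise model, not performance on raw contig translations.

The lizard-style schedule used in tests (38 a modules, inserts of
14/29/44/59 residues on even-numbered modules 22–28, 1-based) follows
the documented progressive lengthening to 59 residues; insert length 5 is
avoided because it is structurally identical to a b module (above).

## Problem sizes and observed behaviour

Validation runs use desk-scale sizes chosen to keep the full suite in a
few seconds: 200 random sequences (≤200 residues) for the brute-force
scanner equivalence, 50 seeded replicates of (ab)×10 for recovery under
10% substitution (mean recall 1.0 observed), and 100 seeded replicates of
(ab)×8 for segregation.

One documented property does not survive its own stated conditions: with
the canonical construction, a and trimmed-b rows differ at only 3 of 27
positions, while i.i.d. 10% substitution over the ~16 unprotected
positions produces within-type p-distances of the same magnitude.
Whenever one row draws an above-average substitution load it becomes a
root-level UPGMA outlier (scipy average linkage produces the same root
split), and purity-at-root fails. Observed: purity = 1.0 in 73/100
replicates at 10% substitution, 92/100 at 5%, 97/100 at ≤4%. The
corresponding acceptance test is kept at the stated 10% bound and fails
honestly; perfect segregation of the real modules is consistent with
this, since real a/b modules differ at many more positions than the
absolutely-conserved catalogue and carry correlated within-type history.

## Limitations

- No gapped alignment of gap-deviant modules (excluded from stacks).
- No six-frame translation or joining of module runs across sequencing
  gaps; regions are reported per contiguous protein sequence.
- Terminal modules: inserts at the very end of a sequence are
  unobservable by design (no delimiting cysteine).
- The a-vs-b ambiguity for modules followed by ≥5 free residues is
  inherent to spacing-only evidence at chaining time.
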