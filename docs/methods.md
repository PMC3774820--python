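# Methods

## The structural model

The search targets the HDV-like double pseudoknot: five paired segments
whose strand order is

    P1a · J1/2 · P2a · P3a · L3 · P3b · P1b · P1.1b · J1/4 · P4 · J4/2 · P2b

P1 (P1a:P1b) and P3 (P3a:P3b) nest; P2 (P2a:P2b) and the 2-bp P1.1
(the first two L3 bases paired with the two bases 3' of P1b) cross the
nesting order and are the pseudoknots.  Self-cleavage occurs at the bond
immediately 5' of P1a, so a fold's cleavage site is fully determined by
where P1a sits.  Offsets are signed against the element boundary in the
28S gene: 0 = element 5' end, negative = within upstream 28S.  Because the
search window spans the boundary (default −45..+5), 28S sequence is
recruited into P1a whenever that is where the complement of P1b lies —
which is precisely how upstream cleavage sites arise.

Descriptor constraints (all config-exposed, defaults in parentheses)
encode the variation observed across R2 ribozymes: P1 4–7 bp with at most
2 mismatches, tolerated only in the distal half of the stem ("top", away
from the cleavage site); P1.1 exactly 2 bp with at most 1 disruption; P2
5–12 bp with at most 1 mismatch among the 5 core-proximal pairs (outer
pairs may mismatch freely but are penalized); P3 4–8 bp with at most 1
mismatch; L3 6–14 nt; J1/2 15–800 nt, contents unconstrained; J1/4 0–2 nt;
P4 a 4–60 nt span; J4/2 2–12 nt.  The invariant positions are: a
catalytic C in J4/2 (taken as the 3'-most C, nearest P2b), the highly
conserved L3 G (operationally: the last L3 base), and a U in the L3
interior available as its reverse-wobble partner.  Under the default
*reject* policy a candidate missing any invariant is discarded — this is
what makes single-base knockouts (catalytic C→U, L3 G→A) empty the fold
list, mirroring their abolition of self-cleavage in vitro.  A *penalize*
policy keeps such folds, flagged, at a score penalty (default 10).

The exact per-position conservation of the published consensus structure
is figure-borne; the package transcribes the prose-level constraints
(catalytic C, L3 G/U, 2-bp P1.1) as invariants and exposes the remaining
consensus positions as a configurable bonus pattern, defaulting to the two
P1.1a cytosines of the consensus active site.

## Search, scoring, determinism

The search anchors on candidate P3/L3 cores (L3-G anchor, interior U, P3
pairing — the most constrained features, which prunes the space), extends
to P1b/P1.1b, enumerates P1a placements inside the window, then closes P2
and partitions the remaining J1/4+P4+J4/2 gap canonically (smallest J1/4,
then smallest P4 whose J4/2 window contains a C).  Scoring is a simple
additive scheme — GC 3, AU 2, GU 1 per pair; −2 per tolerated mismatch;
+2 per matched consensus position; an optional J1/2-length penalty
(default off) — chosen because the source analysis ranks structures
qualitatively; the weights are defaults, not fitted quantities.  Ties
break deterministically: higher score, longer P1, more-upstream cleavage
offset, lexicographically smallest segment layout.  The upstream-offset
preference therefore emerges from stem stability, never from hard-coding
a particular site.

P4 is represented as an unpaired span: the region is highly variable
across elements (absent in all silkmoths, extensively paired elsewhere)
and modelling an optional internal stem would add search dimensions
without affecting cleavage-site prediction.  An internal hairpin is
annotated post hoc (`annotate_p4_stem`) but never scored.  J4/2 length is
bounded 2–12 nt around the HDV-scale joiner, since no range is otherwise
fixed.

`oracle.brute_force_best_fold` re-derives the optimum by flat enumeration
of every segment layout with inline constraint checks and an inline
re-implementation of the score, sharing only the base-pairing primitive
and the fold container with the production search.  It is practical for
sequences of a few hundred nt with J1/2 capped at tens of nt and is the
reference in the search-equivalence tests.

## Junction classification

Reads are presumed top-strand 5'→3' from the start of the 28S flank into
the element (no reverse-complement auto-detection).  Anchoring is exact:
the longest element prefix matching the read suffix locates the element;
the longest 28S prefix locates the junction.  The middle is decomposed as
optional tandem-duplication copies (source: the upstream segment ending at
the junction, or the downstream 28S prefix) allowing substitutions up to a
fraction (default 0.2) of the copy length, followed by a non-templated
insert.  Among competing decompositions the classifier maximizes templated
coverage (matched 28S + duplication-identity + element bases), breaking
ties toward the smaller deletion, upstream over downstream source, then
the longer duplication unit.  Every call satisfies a byte-exact
reconstruction identity, asserted at call time.

Categories: `canonical`, `deletion`, `dup_upstream`, `dup_downstream`,
`nontemplated`, `mixed` (two or more non-canonical features),
`unclassified`.  A junction set is *uniform* when the modal full junction
tuple reaches a threshold fraction, default 0.9 (echoing "over 90%" usage
for endogenous sets); the threshold is a choice, exposed in config.  The
correlation report checks two predictions: offset < 0 ⇒ uniform /
offset = 0 ⇒ variable, and modal duplication length = |offset| (vacuous
when no duplications are observed).

## Synthetic data

**Priming-model simulators.**  Defaults state the study conditions: the
heteroduplex model uses cleavage offset −28 (the most frequent upstream
site) and a 5% duplication-path probability (the observed tandem-
duplication incidence in a duplication-bearing junction survey);
substitutions within duplicated copies default to 5% per base (observed
duplications carry 1–3 substitutions in 21–24 bp); non-templated inserts
are geometric with p = 0.3 (mean ≈ 2.3 nt, matching the short run-off
additions seen at junctions), drawn uniformly over bases.  The
microhomology model uses offset 0, a minimum match of 4 nt, and samples
priming sites with probability proportional to match length (a uniform
alternative sits behind a flag); the geometric tail is resampled a bounded
number of times when no site exists, and reads that still fail are counted
and skipped.

Emitted reads are guaranteed *unambiguous*: a read is resampled if any
alternative decomposition reaches the truth's templated coverage — e.g. a
tail that happens to extend a templated match or to mimic a duplication
source.  The predicate is a standalone enumeration inside the generator,
not a call into the classifier.  Rationale: such reads are inherently
unattributable to any maximum-parsimony reader (the by-eye classification
the analysis emulates faces the same limit), and excluding them makes the
truth table exact.  The resampling perturbs tail statistics only through
rare rejections; calibration tests bound insert-length and
duplication-fraction statistics at Monte-Carlo tolerances.

**Planted ribozymes.**  `generate_ribozyme` writes a descriptor-conformant
fold into a pairing-inert background: loops, joiners and flanks are
adenosine; stems are G/C with deliberate orientation (P3 = G-strand /
C-strand, P2 = C-strand / G-strand, P1a starting with C); L3 is
`CCT…G`; J4/2 carries a single C.  Consequences: (i) no alternative stem
can assemble from background sequence, so the planted fold is the unique
score optimum and recovery is a sharp test; (ii) exactly one catalytic C
and one wobble U are reachable by any candidate core, and the C-strand of
P3 covers the re-anchoring range downstream of the U (enforced by
sampling L3 and P3 jointly with |L3|+|P3| ≥ 14), so the two invariant
knockouts provably empty the search.  What this background does *not*
emulate: realistic base composition, G·U-containing stems, P1 mismatches,
or competing near-optimal folds — recovery rates on planted sequences are
therefore a correctness check on the search machinery, not an estimate of
sensitivity on genomic junctions.  Stem lengths, J1/2 length and the
J1/4+P4+J4/2 gap are sampled per seed within descriptor-compatible ranges
(P1 from {6, 7} by default, the typical stem length).

**Cleavage-site-shift trajectory.**  `simulate_p1_shift` instantiates the
five duplication/mutation states as concrete sequences over a planted
ribozyme whose P1 boundary bases are fixed (`C…G`) so that the scripted
substitutions have determinate pairing consequences, and computes each
state's preference with `compare_p1_candidates` rather than asserting it.

## Comparative layer

Signatures and consensus are aligned by region role, not by sequence:
fixed-width regions map column to column; variable-width regions align
flush to their conserved anchors (P1a to the cleavage side; P2/P3 strands
to their core-proximal ends; L3 with its first two columns left-flushed to
P1.1a, its last column right-flushed to the conserved G, middle
left-flushed).  Gap columns are excluded from frequency denominators.  A
position is a consensus call when its modal base reaches the threshold
(default 0.75) and invariant when every fold carries the same base with no
gap, which makes the invariant set a subset of the consensus set at any
threshold ≤ 1.

## Numerical and interface choices

- Coordinates: 0-based half-open internally; signed offsets in reports
  with 0 at the element boundary.  The published junction diagrams label
  the initial bottom-strand DNA nick "+1"; whether that origin coincides
  with the RNA-offset origin is not stated alongside the known 2-nt
  stagger of the DNA cuts, so the package fixes one origin (element
  boundary = 0) and uses it everywhere.
- Alphabet: DNA/RNA accepted, stored as DNA, U↔T equivalence preserved for
  output; N never matches or pairs.
- All simulators take one integer seed driving a single numpy Generator;
  identical configuration + seed gives byte-identical artifacts; the CLI
  records both in every manifest.
- Problem sizes in the shipped tests and acceptance run — 500 planted
  recoveries, 50 enumerator comparisons, 1000 reads per model per rate,
  10,000 reads for the duplication fingerprint — were chosen as the
  package's standard desk-scale verification batch; all complete in a few
  minutes on one CPU.

## Limitations

- No thermodynamic folding, partition functions or kinetics; the score is
  a combinatorial ranking device.  Consequently no prediction of cleavage
  *rate* or fraction-cleaved, and no modelling of flanking-sequence
  effects on folding efficiency.
- One permissive descriptor covers both the long-J1/2/no-P4 (silkmoth-
  style) and short-P1 (jewel-wasp-style) folds; clade-specific presets can
  be expressed through the config but none are shipped.
- The classifier assumes literal, short junctions reachable by exact
  anchoring; template jumps and 5'-truncated elements fall out as
  `unclassified`, and 3' junctions (uniform in this system) are out of
  scope.
- Junction analyses of specific GenBank accessions require fetching those
  records; the shipped tests and the acceptance run use generated inputs
  only.
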