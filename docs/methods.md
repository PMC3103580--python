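# Methods

This note records the model choices behind `cpscan`: what each stage
assumes, which parameters matter and why their defaults are what they are,
what the synthetic benchmarks do and do not establish, and the numerical
conventions used throughout.

## Coordinates and alphabets

All spans are 0-based, half-open.  Sequences use the 20 canonical amino
acids; the ambiguity codes B, J, O, U, X, Z are rejected by default or, with
`map_ambiguous`, mapped to `X`, which never matches a motif.  Taxonomy
travels in the FASTA header (`id|family|kingdom|organelle[|taxon]`);
the pair (kingdom, organelle) defines the four analysis groups — Bacteria,
Eukarya, Archaea, and Mitochondria as a separate fourth group.  The header
carries no structural class; analyses that need class I/II labels take a
family→class mapping (the synthetic generator provides one).

## Redundancy reduction

Sequence databases over-represent heavily sequenced species, so motif
counts would otherwise be dominated by strain-level duplicates.  Pairwise
similarity is the identity of the best Smith–Waterman local alignment under
BLOSUM62 (gap open 11, extend 1), **normalized by the length of the shorter
sequence**.  Normalizing by aligned columns was considered and rejected: a
single shared 6-mer can yield a short perfect local alignment and an
"identity" of 1.0 between otherwise unrelated sequences, which under single
linkage collapses whole families.  The shorter-sequence convention (the one
CD-HIT uses) keeps a 6-mer match on 300-residue proteins at identity ≈
0.02 while leaving genuine strain variants at ≈ 0.95+.  When no
positive-scoring local alignment exists the identity is 0.  Arguments are
ordered canonically before aligning so the function is exactly symmetric
even when co-optimal tracebacks differ.

Clustering is single linkage at threshold 0.90 within each family;
each cluster is represented by the member with maximal average identity to
the rest (ties: lexicographically smallest id), which makes the clustering
invariant to record order.  An edlib semi-global edit-distance prescreen
skips the exact alignment for pairs that cannot plausibly reach the
threshold (margin 0.15); `prescreen=False` forces the exact path, and the
test suite checks that both paths agree.

## Motif extraction

The extractor treats a family corpus as a Markov-like stream and looks for
substrings whose continuation probability collapses on both sides — the
signature of a conserved island in random context.  The normative rule is
stated in the `cpscan.mex` docstring; the decisions worth recording:

- **Continuation = best extension.**  The boundary closes only if the
  *maximum-count* single-residue extension declines significantly; any
  weaker definition (e.g. the average) would open boundaries inside
  conserved regions whenever usage splits between two continuations.
- **Counts are raw occurrence counts**, overlapping self-occurrences
  included, taken over the redundancy-reduced corpus only.
- **Defaults**: `eta = 0.9` (a 10% relative decline), `alpha = 0.01`
  (binomial one-sided), `l_min = 5` (the field's working definition of a
  deterministic peptide; 4-mers like the HIGH signature are deliberately
  out of scope), `l_max = 30`, `min_support = 3` distinct sequences.  All
  are exposed in `MexParams`.  Emission is monotone in `eta` (lowering it
  only removes boundaries), which the suite asserts.
- **Exact counting at scale.**  Substrings up to length 8 are counted
  exhaustively; longer ones only where their leading 8-mer recurs.  Since
  `c(s)` is monotone under substring, every substring occurring twice is
  still counted exactly — the truncation only discards singletons, which
  the retention rule (`c ≥ 2`) drops anyway.  This keeps a
  100-sequence × 300-residue family at ~1–2 s and a few tens of MB.

## CP space and overlap merging

Per-family motif lists are unified; exact duplicates merge their
provenance, and any motif strictly containing another motif of the union
is removed, leaving an antichain under the substring relation.  Hits of
every CP on every sequence come from a hand-built Aho–Corasick automaton
(tests verify equality with a naive per-CP scan).

Because the extractor emits joined motifs when two conserved regions
co-occur, overlapping hits are statistically coupled.  Merging decouples
them: per sequence, hits sorted by position form maximal chains in which
each hit shares ≥ 1 residue with the running union of its chain.  Two
conventions were genuinely open and are fixed as follows: **book-ended
(adjacent, non-overlapping) hits do not merge** — overlap means a shared
residue — and **a chain of two or more hits of the same CP merges too**
(self-overlap is overlap).  A chain of one hit increments its solo CP; a
longer chain increments a merged feature identified by the spanning
substring, so identical overlap patterns on different sequences share one
global feature.  Conservation — every located hit counted exactly once,
solo or merged — is asserted exhaustively in the suite.

The family × feature matrix divides counted occurrences by family size, so
families of different depths are comparable.

## Family similarity

Pearson correlations between family feature vectors; a constant vector
(possible in small per-kingdom analyses) correlates 0 with a warning.  The
null shuffles each feature's values across families independently —
conserving every feature's total — 100 times, pooling all off-diagonal
correlations into a single background (the analysis treats the background
as one model; a per-pair variant is available via `per_pair=True`).  The
empirical p-value uses the add-one rule `p = (1+#{null ≥ r})/(1+#null)` so
finite shuffles never produce p = 0; pairs with `p < 0.01` are retained.
Per-group analysis re-runs everything from hit location on the group's
sequences; families absent from the group are dropped and reported, and
outlier families can be excluded by a configuration list rather than by
name in code.

## Evolutionary analyses

Origin labels follow the tree topology in which Bacteria is the outgroup
of Archaea + Eukarya: presence sets over the three kingdoms map to
ALL3, AE, B_only, A_only, E_only, BE, or "other" ({Bacteria, Archaea},
which the topology does not expect).  Mitochondrial hits never enter
origin sets.

For mitochondrial enrichment the urn question is genuinely
under-determined; the convention fixed here is: population = CPs hitting
the family's *nuclear* sequences; successes = those hitting exactly one
kingdom within the family (kingdom-specific *in that family*, whatever
they do elsewhere); draw = CPs hitting the family's mitochondrial
sequences that also hit its nuclear ones.  `universe="all"` widens the urn
to all of the family's CPs.  Upper-tail hypergeometric p-values are
BH-adjusted in one batch across the full family × kingdom grid; enrichment
means q < 0.01.  Families without mitochondrial sequences are skipped and
reported.

Class signatures: a CP qualifies for a class when it appears in ≥ 6
families of that class, ≤ 2 families of the other, and its other-class
occurrences are at most `max(3, 5%)` of its total — a skew rule that
tolerates the stray cross-class hit a hard zero would not; all three
thresholds are parameters.  CPs containing configured known signatures
(default stop-list: KMSKS, HIGH) are omitted so the output is *novel*
signatures.  Exclusive shared CPs of a same-class family subset come with
an exhaustive null: the exclusive-CP count of every equal-size subset of
that class.

## Functional sites and cross-corpus sharing

Prevalent CPs appear in **more than** half of the sequences of at least one
family (strict inequality; a configurable stop-list removes known
catalytic signatures).  Site annotations arrive as a TSV of 0-based residue
positions with a priority column; per family only the highest-priority
(smallest value, then lexicographic id) annotated sequence is consulted,
mirroring a "best structure per family" selection.  Distance between a hit
`[start, end)` and a site at `p` is 0 inside the span and otherwise the
number of residues strictly between the site and the nearer boundary; a CP
is "exact" if some hit covers a site, "vicinity" if its minimum distance is
≤ 3.  Significance draws the prevalent CPs from the urn of all CPs hitting
the selected annotated sequences.

Cross-corpus sharing declares two CPs shared on exact string match or full
inclusion, reports the shorter string, and keeps matches occurring in ≥ 20
distinct sequences of *each* corpus; one-substitution variants of equal
length are grouped in a separate Hamming-1 report, never conflated with
sharing.  The residue-shuffle control permutes residues within each
sequence (composition and lengths conserved) and re-runs extraction; a
corpus whose signal is real should yield almost nothing under shuffling.

## Synthetic corpora and what they show

The generator plants deterministic motifs into i.i.d. background residues
(uniform by default), replacing rather than inserting so lengths are
preserved; planted spans are recorded as truth only where they survive
clone-group mutation intact.  Chance motif collisions in the background
are permitted; benchmark designs use motifs of length ≥ 6 over uniform
background, where the expected chance hit rate per sequence is ~300/20⁶ ≈
5 × 10⁻⁶ and exact-count tests are meaningful.  Clone groups derive from a
template by i.i.d. substitutions at rate ≤ 0.05, keeping expected pairwise
identity ≥ 0.9 (two mutated copies differ at ≈ 2× the rate).

The benchmark designs fix the study conditions: recovery uses 10 families
× 100 sequences × 300 residues with insertion probabilities 0.5/0.7; the
evolution design uses 14 families × 40 × 250 with one signature motif per
class, a four-family exclusive quintet, and one family carrying
Bacteria+Mitochondria-restricted motifs against Eukarya(+Archaea)
decoys — group-restricted motifs sit at insertion probability 0.55 so they
stay clear of the 50% prevalence bar, and a block of sub-prevalent decoy
motifs in one class-II family keeps the site-overlap urn rich in CPs that
never touch a site.  Problem sizes were chosen so the full suite and the
acceptance script each run in well under a minute on one CPU.

What passing these benchmarks does **not** show: real protein families are
not i.i.d. background plus deterministic islands — they have compositional
bias, repeats, domain shuffling and phylogenetic correlation between
sequences (the generator's clone groups are the only correlation
structure).  Recovery rates and false-positive counts on the benchmarks
are therefore upper bounds on what identical parameters achieve on real
corpora, and the shuffle control — not the planted recall — is the
realistic guard against compositional artefacts.

## Known limitations

- Motifs are strictly deterministic: no PSSMs, no gaps, no mismatches
  (one-substitution grouping exists only as a report on shared CPs).
- The identity prescreen is heuristic; pathological pairs (high local
  identity inside wildly length-discrepant sequences) could in principle
  be skipped.  The exact path is one flag away.
- The boundary detector assumes approximately stationary background
  statistics within a family; strong low-complexity regions can pass the
  support filter (a poly-Q run is a legitimate deterministic motif by this
  definition, as it should be).
- Hypergeometric urns treat CPs as exchangeable; CPs of very different
  lengths have different chance-hit rates, which the tests ignore.
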