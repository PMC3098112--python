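# Methods

## Problem setting and assumptions

Both classifiers assume the unit of analysis is a *germline derivation
set*: a germline variable-domain sequence, plus derivative sequences that
(a) are unambiguously assigned to that germline, (b) are pre-aligned to it
(equal length, `-` for gaps), and (c) carry a reliable AM/NAM label.
Alignment and annotation correctness is a premise, not something the
package establishes: no aligner is embedded, CDR/FR boundaries and
exposed/buried calls are inputs, and Kabat numbering is out of scope.
Exposure annotations are expected to follow the ≥ 25 % accessible-surface
convention, but any consistent binary call works.

Coordinates are 1-based alignment columns everywhere.  The first
`mask_prefix` columns (default 5) are excluded from every downstream
computation because the corresponding residues may be primer-derived;
masking is logical, so stored sequences are never truncated and masking is
idempotent.  Columns where either the germline or the derivative has a gap
are excluded from mutation calling and from the Bayes products for that
derivative; this is a package decision (the treatment of training-set gap
columns is not otherwise pinned down), chosen so that a gap never counts
as either a mutation or a retention.

## Positional naive Bayes

Per germline and class (sizes n_AM, n_NAM), the mutation probability at
column x is p(x) = (k_x + 1)/(n + 2) with k_x the number of class members
mutated at x — add-one Laplace smoothing, which bounds every probability
inside [1/(n+2), (n+1)/(n+2)] and makes q = 1 − p strictly positive.  A
test sequence is scored by the product over unmasked, ungapped columns of
p at its mutated columns and q elsewhere, once per class; the comparison
AM > NAM decides the label.  Implementation notes:

* Products are accumulated as sums of logs.  At ~110 columns raw products
  reach ~1e-80 and can underflow once class sizes grow; log space changes
  nothing mathematically (verified against brute-force raw products to
  1e-9 relative error in the tests).
* A tie (AM = NAM, which happens under exactly symmetric profiles) is
  resolved to NAM: a sequence is not flagged amyloidogenic without
  positive evidence.
* No class priors enter the comparison; the score is the pure likelihood
  product, so unequal class sizes influence the result only through the
  Laplace denominators.

Leave-one-out cross-validation removes the held-out record from *its own
class only* before re-estimating the profile, then classifies it.
Records whose class has a single member are skipped with a warning and
excluded from the attempted count.  Evaluation is reported per germline
as correct/attempted (C/A) per class; the headline number is the
unweighted (macro) mean ± sd of per-germline C/A, with the pooled micro
accuracy also available.

A caveat worth knowing: on signal-free data this LOO protocol is
*pessimistically* biased at small class sizes.  The held-out record's
class has n − 1 members while the opposing class keeps n, so the held-out
class's retention probabilities q are systematically slightly smaller at
the many unmutated columns, tilting every null fold toward the wrong
class (measured ≈ 0.41 pooled accuracy at 10 + 10 members, ≈ 0.47 at
30 + 30).  Holdout evaluation has no such asymmetry and sits at 50 % on
null data; the chance-level acceptance check therefore uses the holdout
protocol, and a property test asserts that the LOO null is never
*optimistic*.

## Weighted decision tree

Each mutation is routed region → exposure → propensity shift to one of
eight leaves (numbered CDR before FR, exposed before buried, increase
before decrease; leaf 1 = CDR/exposed/Δ, leaf 8 = FR/buried/▽ — the Leaf
object always carries the explicit path, so the numbering is cosmetic).
The shift call uses a per-residue β-sheet propensity scale (ΔΔG,
kcal/mol) whose 20 values are distinct, so every substitution is either
an increase or a decrease; proline's literature value is an inequality
(< −3) and is stored as −3.0, which preserves its rank as the weakest
sheet former — only the ordering enters any computation.

**Weights.**  Mutation-type count matrices (20×20, axes in increasing
propensity order, rows original / columns replacement) are built per
stratum and class; the *exclusive* matrix marks types present in AM
derivatives and absent in NAM ones.  Shift summaries count exclusive
*cells* (types), not occurrence multiplicities.  Edge weights follow the
ratio-to-max convention within each sibling pair: larger count → 1.0,
smaller → smaller/larger rounded half-up to two decimals.  The published
weight table does not follow this convention for three of its seven pairs
(the top region pair and two leaf pairs); those ship with provenance
`published`, with the convention-derived values retained as metadata, and
`derive_weights(..., published=...)` reconciles any summary against a
published table the same way.  When training data leaves a sibling pair
with no exclusive mutations at all, the pair carries no evidence and both
edges stay at 1.0; a smaller count of zero is floored at 0.01 to keep all
path scores positive.

**Per-class normalization.**  The difference matrix is computed on
per-class normalized counts (each class divided by its total mutation
count) so classes of different sizes are comparable; exclusivity is a
raw-count concept and uses raw counts.

**Boosting.**  Leaf separation per germline is the mean per-sequence
fraction of mutations reaching each leaf, AM minus NAM (sequences without
mutations contribute no fraction; boosts are disabled while computing it,
since separation is what selects the boost).  The best-separating leaf is
boosted tenfold, the worst decreased tenfold (factor configurable); ties
break to the lower leaf index, and a flat profile yields an explicit
no-boost entry.  The per-sequence-mean definition of separation is a
package decision — pooled per-mutation fractions would weight long
sequences more.

**Thresholds.**  AM_seq = mean per-mutation score; AM_seq ≥ threshold →
AM (the boundary rule is a package decision; all published thresholds are
positive, and a mutation-free sequence scores 0 → NAM).  Training chooses
the threshold maximizing balanced accuracy over candidate cuts at the
midpoints of adjacent pooled training scores, refining ties to the
midpoint between the highest correctly-excluded NAM score and the lowest
correctly-included AM score.

**Published model.**  Edge weights, boost marks and thresholds for the
twelve germlines ship as `data/published_model.yaml` (version
`published-v1`); training writes new model files and never mutates it.
Two print-level quirks of the published separation table are preserved
and documented in the file: one germline's decreased mark is not its
column minimum, and one germline's minimum is tied across two leaves.
Leave-one-out is deliberately not offered for the tree: weights, boosts
and thresholds would have to be refit per fold, so only resubstitution
and holdout evaluation are provided.

## Synthetic fixtures

The generator emulates the positional structure the classifiers assume: a
uniform random germline; disjoint AM/NAM signature column sets; each
class member mutating at each of its signature columns with `hit_prob`
(default 0.9) and everywhere else with `background_prob` (default 0.02);
AM signature replacements drawn from residues strictly above the germline
residue in propensity order with probability `am_shift_bias` (default
0.9, falling back to the achievable direction with a logged note when the
germline residue is at the end of the scale).  Non-signature columns
cycle deterministically through the four strata unless pinned.  All
randomness flows through a single numpy PCG64 stream, so a (spec, seed)
pair regenerates byte-identical FASTA/annotation/label files.

What the fixtures do *not* emulate: somatic-hypermutation hotspot motifs
and transition biases, realistic germline families, gap-containing
alignments, or correlated mutations.  Passing the recovery tests
therefore shows the estimators and decision rules are implemented
correctly under their own assumptions, not that real antibody sets are
this separable — the published real-data accuracies (60–89 % depending on
protocol and class) are far from the ~100 % the strongly separated
fixtures give.

Default evaluation sizes — 30 + 30 training and 20 + 20 holdout members
for recovery, 10 + 10 train / 10 + 10 test over 200 seeds for the
chance-level suite — keep the whole test run in a few seconds while
giving 4,000 pooled null classifications (3 binomial SE ≈ ±0.024 around
0.5).

## Numerical choices

* Weight rounding: two decimals, half-up (`decimal.Decimal`), matching
  printed-table precision; shift percentages round half-up to integers.
* Tie rules: Bayes tie → NAM; boost-selection ties → lower leaf index;
  threshold ties → the gap-midpoint refinement above.
* Degenerate inputs: empty training class → error naming the class; empty
  exclusive stratum → undefined percentages reported as absent; empty
  test set → empty evaluation table (no division by zero); zero-mutation
  sequence → AM_seq 0, NAM.

## Known limitations

* Exposure and region annotations are trusted as given; disagreement
  between annotation conventions (e.g. different CDR definitions) changes
  strata and therefore tree scores.
* The tree's edge weights are global while boosts and thresholds are
  germline-specific; a germline whose mutation spectrum deviates from the
  pooled trend is served only by its boost/threshold.
* Laplace smoothing with +1/+2 is fixed; no alternative priors are
  exposed.
* The package predicts from positional mutation patterns only — no
  physicochemical, structural or folding-pathway features.
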