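# Methods

## Model

`phenorec` implements user-based collaborative filtering over binary
phenotype profiles.  Every training entity — a patient or a merged
literature document — is a set of phenotype term ids with exactly one
rare-disease label.  A query is itself a phenotype set.  Recommendation
proceeds in three stages:

1. **Scoring.**  The query is scored against every training profile
   with one of four set-similarity coefficients (`tani`, `ol`, `fmg`,
   `ll`; formulas in the README).  Scores are sorted descending, ties
   broken by ascending entity id, so results never depend on storage
   order.  When the query names a training entity, that entity is
   excluded from its own neighborhood.
2. **Neighborhood selection.**  KNN keeps the sorted prefix of length
   `min(k, n)`; ties at the k-th score are resolved by the sort order
   and the list never exceeds `k`.  TPN keeps every neighbor with score
   *strictly* above `t` — a boundary score equal to `t` is excluded.
3. **Aggregation.**  Selected neighbors vote for their labels with
   weight equal to their similarity; per-disease vote totals are
   normalized by the summed weight of all selected neighbors, so the
   score vector is non-negative and sums to 1 whenever the neighborhood
   is non-empty.  Diseases are ranked by score, then by id.

Two aggregation edge cases are fixed by design rather than by the data.
The Fager–McGowan coefficient can be negative (small disjoint sets); a
negative weight would make "similar to nothing" count against a disease,
so weights are clamped at zero.  If every selected neighbor has zero
weight (an all-disjoint KNN neighborhood), the vote falls back to
uniform weights, preserving the probability-vector invariant instead of
dividing by zero.

### Log-likelihood similarity

`ll` builds the 2×2 contingency table of two profiles over a phenotype
universe of size N — cells `k11 = |P_m ∩ P_n|`, `k12 = |P_m \ P_n|`,
`k21 = |P_n \ P_m|`, `k22 = N − |P_m ∪ P_n|` — and computes Dunning's
`G² = 2·Σ k·ln(k·N / (rowsum·colsum))`, with empty cells contributing
zero and a floating-point floor at 0.  G² is unbounded, so it is mapped
onto `[0, 1)` by `1 − 1/(1 + G²)`; this keeps `ll` comparable with the
bounded coefficients and lets TPN thresholds live on one scale.  No sign
correction for negative association is applied: a strongly *anti*
-associated pair also has large G², but such pairs essentially do not
arise between non-empty clinical profiles drawn from a shared universe,
and the tuned thresholds sit far above the independence point.  N is the
number of distinct phenotypes in the fused training table, fixed at fit
time; a query introducing unseen phenotypes transparently enlarges N for
its own comparisons so the contingency table stays valid.

All four measures are total functions: an empty operand returns 0
(ingest guarantees non-empty profiles; a defined zero avoids NaN
propagation through sorting).

## Data fusion

Literature enters as subject–predicate–object predications.  Ingest
keeps a predication iff exactly one side maps (by normalized name or
synonym — lowercase, trimmed, whitespace-collapsed; no stemming) into
the phenotype vocabulary and the other into the disease vocabulary;
phenotype–phenotype and disease–disease assertions are dropped and
counted.  Because a single publication typically asserts one phenotype
for one disease, all documents sharing a disease are merged into one
large document `LIT::<disease_id>` whose profile is the union of their
phenotypes.

* `emr_l` mixes patient and merged-document profiles and permutes
  storage order under a seed.  The permutation affects serialization
  only; all model outputs are order-invariant (tested).
* `emr_pl` first prunes, at (phenotype, disease)-pair granularity,
  every literature pair absent from the EMR pair set, drops documents
  emptied by pruning, then mixes.  Consequently the fused pair set
  always equals the EMR pair set, and pruning is idempotent.

A published pseudocode formulation of the pruning loop removes a
literature pair whenever it differs from *any* EMR pair, which would
delete essentially everything; the implemented rule — retain a pair iff
it occurs in the EMR pair set — is the only reading consistent with the
strategy's purpose and with the invariant that pruned fusion preserves
the EMR association count.

A minimum-support filter removes diseases affecting fewer than
`min_patients` patients (support counted over EMR profiles only;
literature documents of removed diseases go too).

## Parameter tuning

`k` and `t` are tuned by RMSE over leave-one-out rating predictions.
Binary diagnosis data has no explicit zero-ratings, so for each held-out
patient the true diagnosis is rated 1 and `negatives_per_positive`
(default 4) uniformly sampled other diseases are rated 0; the predicted
rating of a disease is its recommendation score, 0 when unranked.  Every
grid point sees identical splits and negative samples (same seed), so
the RMSE curve isolates the parameter.  Default grids: `k ∈ 1..15`,
`t ∈ 0.05..0.95` in steps of 0.05.  The argmin wins; first occurrence on
ties.

## Evaluation

* **Pooled PR curve / PRAUC.**  All (query, candidate) pairs are pooled
  and swept by descending distinct score.  The recall denominator is
  the number of relevant retrieved items plus one unreached relevant
  item per query that retrieved nothing relevant — a query whose true
  disease never appears holds recall below 1 instead of vanishing, and
  the metric is invariant to duplicating queries.  PRAUC is the
  trapezoid over achieved (recall, precision) points, anchored at
  recall 0 with the first point's precision (no optimistic
  interpolation to precision 1); a perfect pooled ranking integrates to
  exactly 1.
* **MAP.**  Average precision per query is the mean of precision@rank
  over the ranks of retrieved relevant items, 0 when none is retrieved;
  MAP averages over all queries, including zero-AP ones.
* **Per-disease P/R/F.**  Over top-1 predictions, a disease is
  evaluated when ≥ `min_patients` (default 3) queries carry it as
  truth.  TP/FP/FN are counted under the active matching criterion, so
  a same-category prediction is a true positive under `category`
  matching; zero-denominator cells score 0; macro-F is the unweighted
  mean over evaluated diseases.
* **Matching criteria.**  `string` compares normalized names and
  synonyms; `concept` compares flat semantic-equivalence keys (a
  deliberate stand-in for hierarchy traversal in a licensed
  terminology — equivalence only, no ancestor/descendant credit);
  `category` tests non-empty intersection of category sets, which is
  reflexive and symmetric but intentionally not transitive.

Relaxing the criterion from `string` through `concept` to `category` is
monotone for MAP and macro-F on corpora whose vocabularies nest the
criteria (same name ⇒ same concept key ⇒ shared category), which the
generator guarantees.  Pooled PRAUC is *not* guaranteed monotone even
then: a newly relevant low-ranked candidate enlarges the recall
denominator and can shrink the area.  The monotonicity claims in the
test suite are therefore stated for MAP and macro-F on pipeline
corpora, and for all three metrics only on a hand-built strictly nested
fixture.

## Synthetic corpus generator

The generator emulates the structure the method assumes, not clinical
language.  Each disease owns an `signature_size`-phenotype signature
laid out by a sliding window over the phenotype universe, so
consecutive diseases share a `signature_overlap` fraction of their
signatures (0 = disjoint partition); this makes the qualitative
difficulty — diseases lacking unique phenotype patterns — a dial.  A
patient keeps each signature phenotype with probability
`1 − phenotype_dropout` (resampled if everything drops, so profiles are
never empty) and gains `noise_phenotypes_per_patient` off-signature
phenotypes.  Each literature document asserts one phenotype–disease
predication, signature-true with probability `lit_fidelity`, uniform
otherwise; a `decoy_fraction` of documents instead emit same-vocabulary
predications that ingest must reject.  Vocabularies carry synonyms at
`synonym_rate`, 1–2 categories per disease from `n_categories`, and a
`concept_twin_fraction` of diseases in consecutive pairs sharing a
concept key and category set, wiring the three matching criteria in
strictly nested form.

Defaults (10 diseases × 8-phenotype disjoint signatures × 20 patients,
10% dropout, 1 noise phenotype, 200 single-predication documents at
full fidelity, 4 categories) define the standard benchmark: hard enough
that similarity matters, small enough that the full test suite and the
acceptance script run in seconds.  All randomness flows through
per-stage `random.Random` instances seeded from `SimConfig.seed`
(string-seeded, platform-independent), so a fixed config reproduces
byte-identical files.

What passing on this generator does *not* show: robustness to
correlated phenotypes, vocabulary-mapping noise, multi-disease
patients, reporting biases of real clinical notes, or citation-skewed
literature.  The generator's independence assumptions (independent
dropout, uniform noise, uniform document-to-disease assignment) are its
main idealizations.

## Experiment groups

An evaluation group is one cell of the 4 measures × 2 neighborhood
rules × 3 fusion strategies grid (24 groups).  `run_group` splits the
EMR disease-stratified (default 80/20) *before* fusion so held-out
queries never leak into literature mixing, fits on the fused table,
queries every held-out patient, and reports PRAUC, MAP, and per-disease
P/R/F with a manifest (config echo, config hash, seeds, fused-table
statistics) sufficient to regenerate it.  `sweep` runs all 24 groups
with fixed per-measure operating parameters (k = 5; TPN thresholds
matched to each coefficient's scale: 0.1 tani, 0.3 ll, 0.3 ol, 0.05
fmg) rather than re-tuning per group, keeping the full grid fast and
bit-reproducible; tuning is exercised separately.

## Known limitations

* Binary profiles only: phenotype frequency, severity, and temporal
  order are discarded by design.
* The concept criterion is equivalence-only; no partial credit for
  ontologically nearby diseases.
* Recommendation scores are normalized votes, not calibrated
  probabilities.
* Exhaustive neighbor scoring is O(n) per query — appropriate at the
  corpus sizes generated here; approximate search is out of scope.
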