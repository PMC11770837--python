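# Methods

## Task and data model

The unit of classification is a `RelationInstance`: one sentence, an
ordered (subject, object) pair of pre-recognized entity mentions, and one
of 23 labels — 22 predicate types (`administered_to` … `uses`,
alphabetical) plus the null label `no_rel`.  Label order is fixed
(alphabetical, `no_rel` at index 22) so that argmax tie-breaking and
probability-vector layouts are reproducible.  Character spans are 0-based
half-open; entity spans within a sentence may be identical, disjoint, or
nested, never partially overlapping.

Two predicates are bidirectional (`associated_with`, `interacts_with`:
swapping arguments preserves meaning) and one pair is mutually inverse
(`A location_of B` ⇔ `B part_of A`).  These equivalences drive corpus
expansion, overlap matching, and store diffing.

The ontological constraint table is a plain set of
(subject semtype, predicate, object semtype) triples with exact three-field
lookup and no inference; it and the semantic type→group map are data files
(TSV), not code, because the corresponding production tables are external
resources the package only consumes.

## Corpus construction

* **Splits.** The fully annotated source ("gs") is split at *sentence*
  level, floor(0.20·n) sentences to train and the rest to test — it is the
  only source on which recall is measurable, so most of it is reserved for
  testing.  The accuracy-annotated sources are split 90/10 train/val at
  instance level (val = floor(0.10·n)).  All partitions are
  sort-then-shuffle under a seeded generator, hence invariant to input
  order.
* **Bidirectional expansion.** Every `associated_with` instance gains a
  reversed duplicate; `location_of`/`part_of` gain a reversed instance
  relabeled with the inverse predicate (relabeling keeps the constraint
  table satisfied); a seeded 10% (rounded to nearest) of `interacts_with`
  instances gain reversed duplicates, since that class is already abundant.
* **Negatives.** Two kinds of `no_rel` instances: extractor false
  positives (`neg_fp`, hard negatives — they satisfied the extractor's own
  constraints), and ordered entity pairs licensed by the constraint table
  that appear in neither gold nor extractor output (`neg_conformant`).
  Duplicate pairs are emitted once, `neg_fp` taking precedence.  A
  per-sentence cap is available but off by default.
* **Entity representations.** `mention` (identity), `semtype`, `semgroup`:
  substitution replaces both argument surfaces with the mention's *primary*
  (first-listed) type or group name and recomputes all spans; non-argument
  mentions keep their text, and mentions nested inside a replaced region
  are dropped.  Full cross-product enumeration over multi-type mentions is
  reserved for the expansion pipeline.
* **Markers.** Four reserved atomic tokens, ASCII-safe by default
  (`<s> </s> <o> </o>`), registered in the tokenizer vocabulary and
  recorded in checkpoints.  Marker insertion supports nested argument
  spans; removing the four markers always reconstructs the sentence.

## Augmentation and contrastive pre-training

Each training sample yields two EDA-style variants (per-token
probabilities, default 0.1 each for synonym replacement, swap, deletion,
insertion — the EDA convention).  Stricter than generic EDA, the marker
tokens and everything inside the argument regions are immutable: the
positive pair must preserve the relation semantics.  The synonym lexicon
is a pluggable flat TSV; a concept-derived lexicon can be supplied but is
not required.  Only the train split is augmented.

Pre-training minimises the temperature-scaled cosine-similarity loss over
batches of 2N projected sentence-summary vectors (N source samples × two
variants; batch size 16; τ = 0.1), mean-reduced over all 2N anchors.  The
denominator excludes the anchor by *identity*, not by value — a value
comparison would misbehave on duplicate vectors.  A batch with a single
source has no negatives; the loss value is still defined (exactly 0) and
the strict default refuses such batches.  The projection head (linear →
dropout 0.1 → tanh) exists only during pre-training and is discarded,
following the convention of the contrastive sentence-embedding literature.
Pre-training and fine-tuning draw from separate seeded random streams, so
the supervised batch sequence is identical with and without pre-training.

## Classifier and training

The classifier head consumes the sentence-summary vector and the
mean-pooled subject and object token spans (marker tokens included).
Class weights are the balanced inverse-frequency form w_c = B/(C·n_c)
(B = batch size, C = classes present, n_c = class count): a description of
this weighting as "the ratio of samples in that class to the total" would
up-weight *frequent* classes, contradicting its stated purpose of helping
minority classes, so the package implements the form that matches the
intent.  Weighted cross-entropy is normalised by the summed weights, so
unit weights reduce exactly to the unweighted mean.

Default hyperparameters: 10 epochs, batch 16, max sequence length 384
(sequences beyond it are excluded, counted, and logged — the skip-with-log
contract), Adam with lr 5·10⁻⁵ and ε 10⁻⁸, no scheduler or weight decay.
That learning rate is a fine-tuning rate for a *pretrained* encoder; the
randomly initialised test backbone trains from scratch, for which the
conventional Adam rate of 10⁻³ is used in the examples and acceptance
runs.  Dropout is active only in training mode; evaluation is
deterministic.

Because no deep-learning framework is assumed, the package carries a
compact reverse-mode autodiff engine on numpy (`semrelclass.nn`) and a
small transformer encoder built on it (2 layers, 64 hidden units, 4 heads
by default; learned positional embeddings; residual + layer norm; tanh
feed-forward).  Gradients are verified against central finite differences
in the test suite.  The `EncoderBackend` contract (atomic marker tokens,
last-hidden-layer states, sentence-summary vector, max length 384) is the
seam where a pretrained biomedical transformer would plug in.

## Threshold calibration

For each non-null class c, candidate thresholds are the sorted unique
validation probabilities of c plus 0.5; the candidate maximising
one-vs-rest F1 (predict c iff p_c ≥ t) wins, ties resolved toward the
smallest candidate, and the result is floored at 0.5.  "Reaches the
threshold" is inclusive (≥), which makes the 0.5 floor attainable.  A
class without positive validation instances defaults to 0.5 with a
warning.  At inference the eligible classes (p_c ≥ t_c) compete by
probability, earlier label order breaking ties; no eligible class means
`no_rel`.  The null label never competes via a threshold — its entry is
fixed at 0.5 and it is purely the fallback.

## Evaluation

Precision/recall/F1 are computed per class and aggregated micro (pooled
TP/FP/FN) and macro (unweighted mean) over the 22 non-null classes; the
null label contributes false positives and negatives to other classes but
no class of its own.  Zero-division yields 0 with a per-class flag.  AUC
is the macro average of one-vs-rest AUCs over all 23 classes (null
included); classes lacking positives or negatives are skipped and logged.
McNemar's paired test uses the exact two-sided binomial p when the
discordant count b + c < 25 and the continuity-corrected chi-square
(|b−c|−1)²/(b+c) otherwise — the standard switch point.  Metric and test
computation route through scikit-learn and statsmodels; the test suite
checks them against hand confusion counts and binomial enumeration.

Two-system overlap partitions each gold relation into found-by-both /
A-only / B-only / neither, matching on (sentence, subject, predicate,
object) under the bidirectional and inverse equivalences above.

## Expansion pipeline

For every sentence with ≥ 2 entities: enumerate all ordered entity pairs
under all (subject type, object type) combinations; keep combinations the
constraint table licenses (so a subject with 2 types and an object with 3,
all licensed, yields 6 inputs); score each with the semantic-type
representation; per ordered pair keep the threshold-eligible prediction
with maximal probability (ties → earlier label order, then earlier
candidate).  Surviving predictions are free to carry any label by default;
a strict mode restricts them to constraint-licensed predicates.  `isa`
predications are kept only if the subject is a descendant of the object in
the supplied concept hierarchy (transitive closure over a parent-child
edge table; the direction is a documented, configurable choice).
Duplicates are deduplicated by canonical key keeping the highest
probability, and the result is partitioned against the existing store into
new / shared / store-only.  Stratified review sampling draws up to a fixed
number of records per predicate (default 23, hence ≤ 506 over 22
categories) without replacement under a seed, and the store-growth
estimate is round(new_count × review_accuracy).

## Synthetic data

The generator emulates the statistical structure the system assumes:
template sentences "context SUBJECT TRIGGER OBJECT context" where a
trigger phrase uniquely determines the relation type (indicator-verb
style: "induces" → `causes`), entity inventories keyed by semantic type, a
constraint table licensing exactly the planted combinations, hard
negatives joining conformant pairs with neutral verbs, configurable class
skew (max/min frequency ratio), and label noise applied last.  Defaults:
2,000 sentences, 8 relation types, 46.5% negatives (the positive share of
the reference dataset is 53.5%), noise 0, skew 1, splits 70/10/20 at
sentence level.  With zero noise a trigger-lookup oracle reaches F1 = 1.0
— the separability guarantee behind the learnability checks.

What the generator does *not* emulate: real PubMed vocabulary and
sentence-length distributions, ambiguous or multi-trigger sentences,
multi-type mentions in training data, anaphora, or annotation
disagreement.  Passing tests therefore demonstrate that the machinery is
correct and trainable, not that the small backbone matches published
accuracy on real text — reaching that requires the original corpora and a
pretrained biomedical encoder.

The SemMedDB-style table builder withholds a seeded fraction of gold
predications from the store (the expansion pipeline should rediscover
them) and supports withholding hierarchy edges for a fraction of `isa`
concept pairs; a withheld pair still transitively reachable through kept
edges is not counted as a violation.

## Problem sizes and acceptance checks

The acceptance script and suite use: 2,000-sentence corpora for
learnability (8 types + null, noise 0, skew 1; 2-layer 64-dim backbone,
10 epochs, Adam 10⁻³), 400-sentence corpora with 30% store hold-out and
40% isa-violation fraction for expansion recovery, 100 random batches for
the contrastive-loss oracle (tolerance 10⁻⁶), and exhaustive search /
confusion counts / binomial enumeration for thresholds, P/R/F1, and
McNemar.  The noisy learnability check compares against a label-frequency
guessing baseline (predict by training-label frequencies): with 10% label
noise the trained model degrades from perfect but stays far above that
baseline.  Published benchmark figures bundled in
`semrelclass.benchmarks` are used purely as inputs to arithmetic
self-consistency checks (harmonic-mean and macro-mean identities, the
expansion estimate); nothing is fitted or tuned to them.

## Known limitations

* The built-in backbone is deliberately tiny; it demonstrates the training
  and inference contracts, not state-of-the-art accuracy on real text.
* The autodiff engine implements exactly the operations the model needs;
  it is not a general framework (no GPU, no mixed precision).
* Whether the production system capped conformant negatives per sentence,
  augmented validation data, or restricted expansion predictions to
  licensed predicates is not documented; all three are configurable with
  conservative defaults (no cap, train-only augmentation, non-strict).
* isa-verification direction (subject below object) is an explicit,
  configurable assumption.
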