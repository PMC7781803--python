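# Methods

## Model and procedure

The package benchmarks two routes from a tokenized clinical record to a
TCM syndrome pattern.

**Direct (MBR).** A record's token sequence is embedded and classified
into one of the 10 pattern labels.  Multiclass probability vectors sum
to 1; the hard label is the argmax, with ties resolved to the
lexicographically first label so predictions are reproducible.

**Hybrid (MBR+RBR).** A multilabel classifier emits a probability per
syndrome element (9 labels); elements with probability ≥ 0.5
(configurable) form the predicted set, which a rule knowledge base
combines into a pattern.  Matching is exact-set-first; failing that,
the rule maximizing the Jaccard overlap wins, provided the overlap
reaches the partial-match floor (default 0.5 — below it no pattern is
assigned, which protects against arbitrary assignments from
single-element predictions).  Ties — including genuinely duplicate
element sets in a user-supplied table — resolve to the lowest integer
priority rank, and every tied rule id is reported so ambiguity stays
visible.  Records with no assigned pattern are *kept and scored as
incorrect*; excluding them would inflate accuracy.

**Rule table.** The shipped table maps each of the 10 pattern names to
an element set readable from the name (e.g. "wind-cold attacking lung"
→ {wind, cold, lung}).  Two patterns need a judgement call: the
wheezing patterns are modeled as latent phlegm plus an external trigger
— cold wheezing {wind, cold, phlegm, lung}, hot wheezing {wind, heat,
phlegm, lung} — which keeps the table injective (hot wheezing is
distinguished from phlegm-heat obstruction in lung by the wind
element), and "deficiency of qi and yin" is the name-derived
{qi-deficiency, yin-deficiency}.  Injectivity is what makes
decompose-then-recompose exact for every pattern and lets the synthetic
generator emit rule-consistent labels.  The table is an editable JSON
file; the engine validates any replacement (coverage, duplicate sets,
unused elements, round trip) rather than assuming these properties.

## Embeddings

Two self-contained numpy trainers, both single-threaded and
deterministic under a fixed seed:

- **Word level** — skip-gram with negative sampling (5 negatives,
  unigram^0.75 noise distribution, linearly decaying learning rate from
  0.025).  Reference configuration: 256 dimensions, window 5,
  min_count 10; every parameter is configurable downward and the
  desk-scale analyses use 32–64 dimensions with min_count 2, since the
  synthetic vocabulary (a few hundred types) needs far less capacity
  than a hospital corpus.
- **Document level** — PV-DBOW: a vector per document trained to
  predict its own tokens (192 dimensions reference).  Defaults are
  heavier (20 epochs, learning rate 0.05, 100 inference epochs)
  because each (doc, word) pair is seen once per epoch.  Crucially,
  downstream classifiers see *inferred* vectors for training and test
  documents alike: vectors stored during training and vectors obtained
  by gradient inference against the frozen word matrix are not
  exchangeable, and mixing them collapses accuracy to chance.

Classical classifiers consume mean-pooled word vectors (the minimal
pooling convention; all-OOV documents map to the zero vector with a
warning).  The CNN consumes index sequences — vocabulary index + 1,
with 0 reserved for padding/unknown — truncated/padded to the 95th
percentile of training-document lengths by default.

## Classifiers

Six families, with reference settings where the protocol states them
and explicitly recorded defaults where it is silent (so every
experiment is self-describing): random forest (1000 trees; analyses
use 200 for speed), XGBoost (100 rounds, depth 6, learning rate 0.3),
linear SVM (multiclass only; probabilities are softmax-normalised
decision margins, which preserves the argmax and the sum-to-1
contract), KNN (k=5), MLP (6 hidden layers with widths in [64, 1024];
reference ramp 1024-512-256-128-64-64, desk-scale runs use
256-128-64-64-64-64), and a text CNN (embedding layer initialized from
the word model and trainable by default, one width-3 convolution with
128 filters, global max-pooling, one dense ReLU layer of 128, softmax
or per-label sigmoid output; Adam, early stopping on a 10% validation
split).  The multilabel roster omits SVM.  XGBoost handles multilabel
output one-vs-rest with constant-column tolerance; RF, KNN and MLP are
natively multilabel.

## Synthetic data: what it emulates, what it does not

The generator draws disease ~ published development-set proportions,
pattern ~ an invented disease-conditional table in which each disease
concentrates on 2–5 clinically plausible patterns (this
informativeness is a study condition, not clinical fact), element set
= the rule table's set for the pattern, and tokens per element ~
Poisson(4, min 1) from per-element lexica of abstract ASCII
identifiers, spread over the five clinical sections, with
disease-correlated chief-complaint tokens and a configurable noise
fraction.  The implied mean element count per record is ≈ 2.64,
bracketing the published corpus density of 2.56.  The token lists are
disjoint by default; a configurable overlap fraction creates controlled
label ambiguity for stress tests.

What passing tests on this generator show: the pipeline machinery —
embedding, classification, rule reasoning, evaluation — recovers known
structure under the stated conditions.  What they do not show:
performance on real EMRs, whose symptom co-occurrence, negations,
section structure and class imbalance the generator does not model.
The published headline accuracies derive from private hospital data and
are context, not test targets.

## Experiment design choices

- **Corpus comparison.**  The diagnosis token's marginal value is only
  identifiable when the narrative does not already encode the disease:
  with disjoint element lexica and disease-correlated symptom tokens,
  corpus 1 determines the pattern and the paired delta is ≈ 0
  regardless of priors.  The comparison experiment therefore uses
  element-lexicon overlap 0.8, noise 0.2 and no disease-symptom
  tokens; under uninformative (uniform) disease→pattern tables the
  same pairing yields |delta| < 0.02, confirming the effect is the
  token's information and not an artifact of the pairing.
- **Scaling analysis.**  Grid cells draw balanced per-pattern samples
  (disease sampled from the Bayes inversion of the conditional table),
  split 4:1, and record one test accuracy per cell, with class subsets
  fixed per column from the seed.  The driver uses an
  estimation-limited regime (wide lexicon of 40 tokens/element, sparse
  evidence of ~1.5 tokens/element per record, 40% noise) with a fast
  token-count random-forest pipeline, so the learning curve rises
  slowly enough for crossings to be observable at desk scale.
  Censored columns (threshold never reached) are excluded from the OLS
  fit and reported.  The crossing-then-OLS procedure itself is
  validated by recovering a known line (slope 35, intercept 110, noise
  sd 20) within [25, 45].
- **Repeated CV.**  95% CIs are the empirical 2.5/97.5 percentiles of
  the folds × repeats score distribution (distribution-free; a
  normal-approximation option exists).  Fold assignment reshuffles
  every repeat from the seed stream.
- **Hybrid reporting.**  In MBR+RBR reports, `accuracy` is end-to-end
  pattern accuracy while precision/recall/F1 are support-weighted
  per-element values — the convention under which element precision
  (~0.99 at high signal) exceeds pattern accuracy, since one missed
  element usually breaks the exact rule match.
- **Averaging** is support-weighted (not macro) throughout.

## Numerical and degenerate-input conventions

Zero-denominator precision/recall/F1 are 0.  Multiclass ties go to the
lexicographically first label; the multilabel threshold is inclusive
(≥).  Empty predicted element sets propagate as "no pattern" and score
as incorrect.  Splits assign remainder rows to train (14,075 at 4:1 →
2,815 test records); stratified splitting errors out when a class has
fewer records than ratio parts, and repeated CV errors out when a
class has fewer records than folds.  The CNN pads sequences shorter
than its kernel and keeps the padding embedding row at zero.  Noise
tokens are inserted at a Poisson rate calibrated so their expected
fraction of the final document equals `noise_token_rate`.

## Problem sizes

The analyses run at 2,000-record development sets (1,600/400 split),
500-record external sets, 32-dimensional embeddings and reduced tree
counts/layer widths — sizes at which every arm trains in seconds while
the qualitative structure (CNN ≥ classical arms ≥ chance, corpus-2 >
corpus-1 under ambiguity, positive crossing-size slope) is stable
across seeds.

## Known limitations

No Chinese segmentation is built in (the segmenter is pluggable; the
pipeline operates on pre-tokenized sequences).  The embedding trainers
are corpus-scale, not Wikipedia-scale; external pretrained vectors can
be loaded from the standard word2vec text format.  The scaling fits
describe the synthetic regime probed, not a universal sample-size law.
Doc2Vec arms are consistently weaker than Word2Vec arms at desk scale,
mirroring their ordering at full scale but with a larger gap.
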