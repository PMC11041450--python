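# Methods

This note documents the models and procedures implemented in `newsqual`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not establish.

## Task and data model

Each news article carries a three-valued rating per quality criterion
(cost, harm, conflict of interest). Ratings are binarized for
classification: *satisfactory* → 1, *unsatisfactory* and *not applicable* →
0, so each criterion is an independent binary document-classification task.
News stories and press releases are pooled; the source type is retained as
metadata only. Corpora are JSONL (one UTF-8 object per line) with 0-based,
half-open character offsets used for every sentence span.

Sentence splitting is rule-based: a run of `.?!` ends a sentence when
followed by whitespace and a capital (or an opening quote before one),
with an abbreviation exception list (Dr., Mr., Mrs., Ms., St., U.S., e.g.,
i.e., Fig., No., vs.). A model-based splitter would handle more edge
punctuation but would not be deterministic across versions; determinism is
worth more here because gold evidence is addressed by sentence index.

## Text normalization

The chain is: accent stripping (NFKD, combining marks dropped, with an
index map so token offsets still point into the source text), lowercasing,
tokenization, removal of tokens containing digits, stop-word removal
against a list frozen in the repository (external lists drift), possessive
stripping, then lemmatization (irregular table + plural folding) followed
by Porter stemming. Lemmatize-then-stem is fixed as the order; the two are
listed without an order in the source method, and this order is
deterministic and slightly more aggressive. The composed normalizer is
iterated to a fixed point (bounded at 5 rounds) because a single Porter
pass is not idempotent on all of its own outputs (e.g. a stem ending in a
bare "s" loses it on a second pass); the fixed point makes preprocessing
idempotent, which the matching layer relies on — keyword phrases and
sentence tokens are compared in the same normalized space, so "risks"
matches "risk" and "side effects" matches the "side effect" phrase.

## TF–IDF

Unigrams + bigrams; vocabulary capped at `max_features` n-grams chosen by
total corpus count with lexicographic tie-breaks; idf(t) =
ln((1+N)/(1+df(t))) + 1 (the smoothed variant); raw term counts; L2
normalization per document; out-of-vocabulary n-grams ignored. The formula
is implemented directly (and cross-checked against scikit-learn's
TfidfVectorizer in the tests on tie-free corpora) because the vocabulary
tie-break and the JSON round-trip of vocabulary + idf need to be exact for
the explainer's enumeration oracle to be well-defined. Bigrams are included
because the keyword layer contains two-word phrases ("side effect",
"adverse reaction") that must be representable as single features.

## Document classifiers

Four families: logistic regression, multinomial naive Bayes, SVM (with
sigmoid probability calibration, since SVC has no native probabilities),
and random forest. Randomized search samples a family uniformly, then each
hyperparameter uniformly from a declared per-family grid, crossed with a
feature-count grid; each trial is scored by stratified 5-fold mean AUC and
the argmax is returned (earliest trial wins ties). Folds are stratified
throughout — with a ~2% positive class for the conflict criterion,
unstratified 10-fold splits would regularly lose the minority class. A
`balanced_class_weight` flag exists for that stress configuration but is
off by default.

Shipped default specs are per-criterion random forests: cost — 1000 word
features, 600 trees, min_samples_split 2, min_samples_leaf 4, max_features
sqrt, max_depth 10, no bootstrap; harm — 2000 features, 1400 trees,
min_samples_split 10, min_samples_leaf 4, max_depth 90, no bootstrap;
conflict — 1000 features, 1200 trees, min_samples_split 10,
min_samples_leaf 1, max_depth 20, bootstrap. (A historical "auto" value for
max_features means sqrt for classification forests and is shipped as
"sqrt".) The random-forest search grid contains every default value, so
the defaults are reachable by search.

Evaluation is repeated stratified k-fold (default 50 × 10); the TF–IDF
model is refit inside every training fold, so no vocabulary or idf
information from held-out documents can leak into training. AUC uses the
rank-sum (Mann–Whitney) formulation with average ranks for ties, which
equals the trapezoidal ROC area; scikit-learn's `roc_auc_score` serves as
the independent oracle in tests, never as the implementation. The decision
threshold for the binary label is 0.5; probabilities are retained for the
explanation layer.

## Perturbation surrogate (document explanation)

The explainer is implemented in this package. The perturbation unit is the
*distinct in-vocabulary n-gram* (type level), not the token position: this
matches feature removal semantics and keeps the mask length equal to the
number of distinct document features. The pipeline: the first mask is
all-ones (intact document); the remaining `n_samples − 1` masks keep each
bit independently with probability 0.5; each masked variant re-normalizes
the document vector to unit L2; the black box is queried in one batch;
samples are weighted by exp(−d²/σ²) with d the cosine distance between the
mask and the all-ones mask; a weighted ridge regression (intercept
unpenalized) of the probabilities on the mask bits yields signed
per-feature weights. Positive weight supports the satisfactory class.

Defaults: kernel width σ = 0.75 on cosine distance, ridge penalty 1.0,
5000 samples — common practice for this family of explainers, all
config-exposed. `exact_surrogate` solves the same weighted ridge problem
over all 2^u masks of a ≤12-feature document and is the enumeration oracle
for the sampled path: with a black box linear in mask space and a vanishing
penalty it recovers the true coefficients exactly, and the sampled
explainer must rank-agree with it (Spearman ≥ 0.95 at 5000 samples in the
acceptance suite).

Global rankings are provided both ways — mean signed surrogate weight over
documents predicted satisfactory, and the estimator's intrinsic feature
importances — because either aggregation is defensible and they agree on
top entries for separable data; both are exposed rather than one chosen.

## Hybrid highlighting

Curated keyword lists: cost — price, cost, charge, insurance, pay; harm —
side effect, adverse reaction, adverse event, complication, risk; conflict
— fund, sponsor, grant, spokesman, professor, director. Merging keeps only
positive-weight surrogate keywords (those supporting a satisfactory
prediction); a phrase present in both lists collapses onto the curated
tier. "Curated outranks surrogate" is encoded lexicographically as a
(tier, magnitude) sort key rather than as an inflated numeric weight —
this encodes the dominance rule exactly, with no magic constant that a
large surrogate weight could overcome. Within a tier, magnitude sums a
fixed 1.0 bonus per curated-phrase occurrence plus |weight| per surrogate
occurrence (summation rather than max; config-exposed). Ties break toward
the earlier sentence. Unmatched sentences are never highlighted, so a
window of k may return fewer sentences.

The known failure mode is retained, not patched: a benefit-phrased
sentence ("reduces the risk of fractures by 24 percent") or a stock-price
sentence shares criterion keywords and gets highlighted; the tests assert
this happens on confounder-bearing corpora, documenting the limitation.

## Typology pipeline

Extraction records hold two extractors' picks and an optional referee
decision; a sentence is evidence iff both extractors picked it, or exactly
one did and the referee approved. Disagreement without a referee is an
error naming the sentence. The agreement report exposes the raw counts
(n_a, n_b, n_both, n_final) and `simple_agreement_pct` = 100·n_both/n_final
— the share of adjudicated positives both extractors found independently;
the counts are all present so other ratios can be formed if preferred.

The balanced dataset takes all gold evidence sentences as positives and an
equal number of sentences sampled uniformly without replacement from all
remaining sentences corpus-wide (corpus-wide rather than per-article: at
small n it covers more articles). The sentence classifier reuses the
TF–IDF + family + search machinery at sentence granularity. Highlighting
ranks sentences by evidence probability with a 0.5 floor (config-exposed):
sub-threshold sentences never fill the window, avoiding the failure mode
of padding the window with weak candidates.

## Accuracy curves and window selection

Highlighting accuracy is pooled (micro): 100 × (highlighted sentences that
are gold) / (all highlighted sentences), over every test article, each
truncated to its top-k; articles with no highlights contribute to neither
count, and zero total highlights is reported as not-applicable rather
than 0. Pooling (vs. a per-document macro average) is config-exposed.

The window is the largest k whose accuracy stays **at or above** the
threshold for every j ≤ k (prefix rule, inclusive comparison). Inclusive
is the only reading consistent with published spectra in which cells of
exactly 75.00 count as passing; the prefix rule (rather than "last k
meeting the threshold") is used because a window is a usable range — every
smaller setting must also meet the bar. On the published typology spectra
this selects windows of 2 (cost), 4 (harm) and 1 (conflict) sentences at
the 75% threshold, which `scripts/acceptance.py` recomputes.

## Synthetic corpus generator

The generator emulates the statistical structure the system assumes, not
real language. Defaults mirror the observed study conditions: 10–60
sentences per article; satisfactory fractions 0.25 (cost), 0.45 (harm) and
0.02 (conflict) — the conflict imbalance is a stress configuration, and
tests use balanced 0.5 fractions for statistical power; 1–6 evidence
sentences per positive article; a 0.3 per-criterion confounder rate
(the failure-mode sentences appear in a minority of articles); a 120-word
neutral background vocabulary of deterministic CVCV pseudo-words disjoint
from every criterion keyword and stop word. Criterion labels are sampled
independently per criterion. Templates are closed slot-fillers
(intervention numbers, company and surname lists) — no external word
lists — so identical seeds give byte-identical corpora.

Feasibility: a config whose minimum evidence count cannot fit in the
maximum article length errors immediately; when several simultaneously
satisfied criteria compete for room in one short article, per-criterion
evidence counts are sampled in range and clipped to remaining capacity, so
the defaults never abort while the in-range postcondition holds.

What passing on this benchmark shows: that the pipeline recovers planted
evidence when the signal is lexically separable, that the dominance and
dilution properties hold mechanically, and that the documented confounder
failure mode occurs. What it does not show: robustness to paraphrase,
discourse structure, topic drift, or any property of real health news —
the templates have no syntax variation beyond slots, and background text
is semantically empty.

## Problem sizes and numerical choices

The study-scale tests use 400 training and 120 held-out articles per run
(20 satisfactory test cases per criterion for highlighting accuracy,
mirroring a 20-test-case evaluation design), surrogate budgets of 1000
samples for highlighting harnesses and 5000 where the sampled-vs-exact
guarantee is asserted, and 5 × 5-fold repetition (n = 500) for the
permuted-label null check, which must land in [0.45, 0.55] mean AUC.
Ridge systems are solved by dense Cholesky-backed `numpy.linalg.solve`;
the enumeration oracle is capped at 12 features (4096 masks). Degenerate
inputs are defined, not exceptional: empty documents vectorize to the zero
vector and explain to an empty keyword list with a valid probability;
all-OOV masks produce the zero vector; a document with no keyword matches
highlights nothing.

## Known limitations

- The keyword tier cannot distinguish benefit-phrased risk sentences or
  stock-price sentences from genuine evidence (by design; documented).
- The sentence splitter's abbreviation list is finite; unseen
  abbreviations split early. Gold indices are validated on load, so a
  mismatch surfaces as an error rather than silent misalignment.
- The lemmatizer folds plurals only; irregular verb inflection is left to
  the stemmer and can under-merge rare forms.
- Surrogate weights are local: they explain one document's prediction and
  are averaged, not summed, for the global view; no stability guarantee
  across seeds is made beyond the rank-agreement bound.
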