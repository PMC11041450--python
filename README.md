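# newsqual

Criteria-based quality evaluation of health news with interpretable,
sentence-level evidence highlighting.

Health news is commonly appraised against editorial quality criteria: does
the article discuss the **costs** of the intervention, does it explain or
quantify its **harms**, does it identify **conflicts of interest**? Each
criterion is rated *satisfactory* / *unsatisfactory* / *not applicable*, and
a classifier can automate the rating — but a bare probability is hard to
trust. `newsqual` pairs per-criterion document classifiers with two ways of
*showing* the evidence behind a rating, for researchers in health
informatics and for anyone building reader-facing news-quality tools.

## What it computes

**Document classification.** Bodies are normalized (accent stripping,
lowercasing, digit/punctuation removal, stop-word removal, lemmatization
then Porter stemming) and vectorized with TF–IDF over unigrams + bigrams:
w(t, d) = tf(t, d) · (ln((1+N)/(1+df(t))) + 1), L2-normalized per document.
Four model families (logistic regression, naive Bayes, SVM, random forest)
are available, with randomized hyperparameter search scored by stratified
5-fold mean AUC and evaluation by repeated stratified k-fold AUC (default
50 × 10-fold). AUC uses the rank-sum (Mann–Whitney) formulation. Shipped
default specs are per-criterion random forests (1000 / 2000 / 1000 word
features for cost / harm / conflict).

**Hybrid highlighting.** A self-contained perturbation surrogate (the
LIME mechanism) explains one document: binary masks over the document's
distinct in-vocabulary n-grams are sampled, the black box is queried on each
masked variant, samples are weighted by exp(−d²/σ²) on cosine distance in
mask space, and a weighted ridge regression attributes the prediction to
individual n-grams. Positive-weight keywords are merged with a curated
per-criterion keyword list (curated entries strictly outrank surrogate
ones), and sentences are ranked by (tier, matched-keyword weight).

**Typology highlighting.** Evidence sentences collected by two extractors
(with referee adjudication of disagreements, plus interannotator-agreement
reporting) train a balanced sentence-level evidence classifier through the
same TF–IDF machinery; sentences are ranked by evidence probability, with a
0.5 probability floor.

**Window selection.** Highlighting accuracy — the percentage of highlighted
sentences that are genuine evidence, pooled over the test set — is computed
at each window size k = 1..K; the selected window is the largest k whose
accuracy stays at or above a threshold (default 75%) for every j ≤ k.

Because the original reviewed-news corpus is no longer available, the
package ships a seeded synthetic corpus generator that emulates its
structure: minority satisfactory classes, 1–6 planted evidence sentences
per positive article drawn from criterion lexicons, keyword-sharing
confounder sentences (benefit-phrased "reduces the risk of …" for harm,
stock-price wording for cost), and neutral background text, with gold
evidence indices recorded.

## Worked example

```bash
cat > cfg.yaml <<'YAML'
generator:
  n_articles: 120
  satisfied_fraction: {cost: 0.5, harm: 0.5, conflict: 0.5}
  sentences_per_article: [8, 14]
  confounder_rate: 0.3
YAML

newsqual simulate --config cfg.yaml --out sim --seed 42
newsqual train-doc      --corpus sim/corpus.jsonl --criterion harm --out doc-harm  --seed 42
newsqual train-typology --corpus sim/corpus.jsonl --criterion harm --out sent-harm --seed 42

newsqual highlight --approach hybrid --model doc-harm --corpus sim/corpus.jsonl \
    --article-id syn-2131802971-00003 --criterion harm --k 2 --seed 42 --out hl.json
```

The highlighted sentences (from `hl.json`, tier and score shown):

```
manual 2.508 | Doctors warned of complications and a small risk of permanent nerve damage.
manual 1.155 | About 57 percent of patients reported an adverse reaction during the study.
```

Both are gold evidence sentences for the harm criterion; `manual` means a
curated keyword ("complication", "risk", "adverse reaction") anchored the
match, and the score adds 1.0 per curated-keyword occurrence plus the
surrogate weights of the other matched n-grams. The corresponding
explanation (`newsqual explain …`) reports the classifier probability
(0.953 here) and the top surrogate keywords — stems such as `complic`,
`adver`, `doctor warn` — each with its signed contribution to the
satisfactory prediction.

Evaluating both approaches on the corpus's satisfactory articles:

```bash
newsqual evaluate --corpus sim/corpus.jsonl --doc-model doc-harm \
    --sent-model sent-harm --criterion harm --kmax 6 --seed 42 --out eval
```

writes per-k accuracy curves and the selected windows:

```
k   hybrid   typology
1   100.00   100.00
2    88.98   100.00
3    83.43   100.00
...
windows at 75%: hybrid=5, typology=6
```

The hybrid curve dilutes as k grows because confounder sentences share the
"risk" keyword without being evidence; the sentence classifier, trained on
evidence vs. non-evidence sentences, is not fooled by them in this run.

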