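"""Local surrogate explainer: mask sampling, ridge recovery, enumeration
oracle, and planted-keyword recovery on the synthetic corpus."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from newsqual.corpus import Criterion, NewsArticle, Rating
from newsqual.explain import (
    _all_masks,
    exact_surrogate,
    explain_document,
    fit_surrogate,
    global_ranking,
    kernel_weights,
    mask_to_vector,
    perturb_masks,
)
from newsqual.text import fit_tfidf, preprocess, vectorize


class LinearMaskBox:
    """Black box whose probability is exactly linear in feature presence."""

    def __init__(self, tfidf, coefs: dict[str, float], intercept: float = 0.1):
        self.tfidf = tfidf
        self.intercept = intercept
        self.weights = np.zeros(len(tfidf.vocabulary))
        for gram, w in coefs.items():
            self.weights[tfidf.vocabulary[gram]] = w

    def predict_matrix(self, X):
        presence = (X != 0).astype(float).toarray()
        return self.intercept + presence @ self.weights


@pytest.fixture(scope="module")
def linear_box():
    words = "aqua brick coral dune ember fjord grove heath islet joule".split()
    docs = [preprocess(" ".join(words)), preprocess(" ".join(words[:5]))]
    tfidf = fit_tfidf(docs, max_features=len(words))  # unigrams fill the cap
    coefs = {w: c for w, c in zip(sorted(tfidf.vocabulary), np.linspace(-0.4, 0.5, 10))}
    article = NewsArticle(article_id="toy", body=" ".join(words) + ".")
    return LinearMaskBox(tfidf, coefs), article, coefs


class TestPerturbMasks:
    def test_first_mask_is_all_ones(self):
        masks = perturb_masks(3, 1, seed=0)
        assert masks.shape == (1, 3)
        assert np.all(masks == 1)

    def test_bit_keep_frequency_near_half(self):
        masks = perturb_masks(10, 4000, seed=1)
        freq = masks[1:].mean(axis=0)
        assert np.all((freq >= 0.47) & (freq <= 0.53))

    def test_seed_determinism(self):
        assert np.array_equal(perturb_masks(6, 50, seed=3), perturb_masks(6, 50, seed=3))

    def test_invalid_sizes_error(self):
        with pytest.raises(ValueError):
            perturb_masks(0, 5, seed=0)


class TestMaskToVector:
    def _doc_vector(self):
        docs = [preprocess("alpha beta gamma"), preprocess("alpha delta")]
        tfidf = fit_tfidf(docs, max_features=20)
        return vectorize(tfidf, preprocess("alpha beta"))

    def test_all_ones_mask_is_identity(self):
        vec = self._doc_vector()
        out = mask_to_vector(vec, np.ones(vec.nnz, dtype=int))
        np.testing.assert_allclose(out.toarray(), vec.toarray(), atol=1e-12)

    def test_all_zeros_mask_gives_zero_vector(self):
        vec = self._doc_vector()
        assert mask_to_vector(vec, np.zeros(vec.nnz, dtype=int)).nnz == 0

    def test_partial_mask_renormalizes(self):
        vec = self._doc_vector()
        mask = np.ones(vec.nnz, dtype=int)
        mask[0] = 0
        out = mask_to_vector(vec, mask)
        assert np.sqrt(out.power(2).sum()) == pytest.approx(1.0)


class TestFitSurrogate:
    def test_recovers_linear_blackbox_exactly_under_enumeration(self):
        rng = np.random.default_rng(4)
        u = 8
        true = rng.normal(size=u)
        masks = _all_masks(u)
        probs = 0.3 + masks @ true
        w = kernel_weights(masks)
        coef = fit_surrogate(masks, probs, w, ridge_penalty=1e-8)
        np.testing.assert_allclose(coef, true, atol=1e-6)

    def test_constant_blackbox_gives_zero_weights(self):
        masks = _all_masks(5)
        w = kernel_weights(masks)
        coef = fit_surrogate(masks, np.full(len(masks), 0.7), w, ridge_penalty=1.0)
        np.testing.assert_allclose(coef, 0.0, atol=1e-9)

    def test_non_varying_feature_gets_zero_weight(self):
        # feature 0 always on: the unpenalized intercept absorbs it
        masks = np.hstack([np.ones((16, 1)), _all_masks(4)])
        rng = np.random.default_rng(0)
        probs = rng.random(16)
        coef = fit_surrogate(masks, probs, np.ones(16), ridge_penalty=1.0)
        assert coef[0] == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_design_errors(self):
        masks = np.ones((10, 3))
        with pytest.raises(ValueError, match="degenerate"):
            fit_surrogate(masks, np.ones(10), np.ones(10))


class TestExactSurrogate:
    def test_single_feature_matches_two_point_closed_form(self):
        words = ["quartz"]
        docs = [preprocess("quartz onyx"), preprocess("quartz")]
        tfidf = fit_tfidf(docs, max_features=1)
        box = LinearMaskBox(tfidf, {"quartz": 0.4}, intercept=0.2)
        article = NewsArticle(article_id="one", body="quartz.")
        got = exact_surrogate(box, article, ridge_penalty=1e-10)
        # hand solution of the weighted 2-point least squares: slope =
        # f(on) - f(off) regardless of weights when lambda -> 0
        assert got["quartz"] == pytest.approx(0.4, abs=1e-6)

    def test_zero_feature_document_gives_empty_weights(self):
        docs = [preprocess("quartz onyx"), preprocess("quartz")]
        tfidf = fit_tfidf(docs, max_features=5)
        box = LinearMaskBox(tfidf, {})
        article = NewsArticle(article_id="blank", body="entirely unrelated words.")
        assert exact_surrogate(box, article) == {}

    def test_too_many_features_errors(self, linear_box):
        box, article, _ = linear_box
        with pytest.raises(ValueError, match="max_features"):
            exact_surrogate(box, article, max_features=3)

    def test_recovers_linear_coefficients(self, linear_box):
        box, article, coefs = linear_box
        got = exact_surrogate(box, article, ridge_penalty=1e-8)
        for gram, w in coefs.items():
            assert got[gram] == pytest.approx(w, abs=1e-6)


class TestExplainDocument:
    def test_sampled_matches_exact_in_rank(self, linear_box):
        box, article, _ = linear_box
        exact = exact_surrogate(box, article)
        rhos = []
        for trial in range(5):
            expl = explain_document(box, article, n_samples=5000, top_m=None,
                                    seed=100 + trial)
            sampled = {kw.ngram: kw.weight for kw in expl.keywords}
            grams = sorted(exact)
            rho = spearmanr([exact[g] for g in grams],
                            [sampled[g] for g in grams]).statistic
            rhos.append(rho)
        assert min(rhos) >= 0.95

    def test_locality_weights_only_for_document_ngrams(self, harm_model,
                                                       separable_corpus):
        article = separable_corpus.articles[0]
        doc_grams = set()
        vec = vectorize(harm_model.tfidf, preprocess(article.body))
        for c in vec.indices:
            doc_grams.add(harm_model.tfidf.ngram_for(int(c)))
        expl = explain_document(harm_model, article, n_samples=300, top_m=None, seed=0)
        assert {kw.ngram for kw in expl.keywords} <= doc_grams

    def test_planted_keyword_recovered_with_positive_weight(
        self, harm_model, separable_corpus
    ):
        article = next(
            a for a in separable_corpus
            if a.ratings[Criterion.HARM] is Rating.SATISFACTORY
        )
        expl = explain_document(harm_model, article, n_samples=2000, top_m=10, seed=7)
        harm_grams = {"side effect", "risk", "complic", "advers"}
        positive = {kw.ngram for kw in expl.keywords if kw.weight > 0}
        assert any(
            any(h in g for h in harm_grams) for g in positive
        ), f"no planted harm keyword among {sorted(positive)}"

    def test_negative_article_has_no_planted_keyword_support(
        self, harm_model, separable_corpus
    ):
        article = next(
            a for a in separable_corpus
            if a.ratings[Criterion.HARM] is not Rating.SATISFACTORY
            and a.ratings[Criterion.COST] is not Rating.SATISFACTORY
            and a.ratings[Criterion.CONFLICT] is not Rating.SATISFACTORY
        )
        expl = explain_document(harm_model, article, n_samples=2000, top_m=5, seed=8)
        top_positive = [kw.ngram for kw in expl.keywords if kw.weight > 0][:5]
        assert not any("side effect" in g or g == "risk" for g in top_positive)

    def test_empty_document_returns_probability_and_no_keywords(self, harm_model):
        article = NewsArticle(article_id="empty", body="the of and.")
        expl = explain_document(harm_model, article, n_samples=100, seed=0)
        assert expl.keywords == []
        assert 0.0 <= expl.predicted_prob <= 1.0

    def test_seeded_reproducibility(self, harm_model, separable_corpus):
        article = separable_corpus.articles[1]
        e1 = explain_document(harm_model, article, n_samples=400, seed=9)
        e2 = explain_document(harm_model, article, n_samples=400, seed=9)
        assert [(k.ngram, k.weight) for k in e1.keywords] == [
            (k.ngram, k.weight) for k in e2.keywords
        ]


class TestGlobalRanking:
    def test_planted_evidence_ngrams_dominate_top_ten(self, harm_model,
                                                      separable_corpus):
        ranking = global_ranking(
            harm_model, separable_corpus, Criterion.HARM,
            method="lime_aggregate", top=10, n_samples=400, seed=0,
        )
        harm_stems = ("side", "effect", "risk", "complic", "advers", "bleed",
                      "nausea", "drug", "event", "reaction", "symptom",
                      "infect", "nerv", "damag", "sever", "patient", "doctor",
                      "warn", "dizzi", "headach", "trial", "particip",
                      "record", "investig", "intern", "carri", "seriou",
                      "percent", "report", "studi", "case")
        hits = sum(
            1 for kw in ranking.keywords
            if any(st in kw.ngram for st in harm_stems)
        )
        assert hits >= 5

    def test_model_importance_agrees_with_aggregate_on_top_entries(
        self, harm_model, separable_corpus
    ):
        agg = global_ranking(harm_model, separable_corpus, Criterion.HARM,
                             method="lime_aggregate", top=5, n_samples=400, seed=0)
        imp = global_ranking(harm_model, separable_corpus, Criterion.HARM,
                             method="model_importance", top=5)
        overlap = {k.ngram for k in agg.keywords} & {k.ngram for k in imp.keywords}
        assert len(overlap) >= 3

    def test_top_zero_is_empty(self, harm_model, separable_corpus):
        out = global_ranking(harm_model, separable_corpus, Criterion.HARM,
                             method="model_importance", top=0)
        assert out.keywords == []

    def test_ranking_capped_at_thirty(self, harm_model, separable_corpus):
        out = global_ranking(harm_model, separable_corpus, Criterion.HARM,
                             method="model_importance", top=30)
        assert len(out.keywords) <= 30
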