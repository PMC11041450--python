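"""Typology pipeline: adjudication, agreement, sentence classifier,
probability-ranked highlighting."""

import pytest

from newsqual.corpus import Criterion, NewsArticle, Rating
from newsqual.synth import (
    GeneratorConfig,
    Lexicon,
    generate_corpus,
    generate_sentence_dataset,
)
from newsqual.typology import (
    ExtractionRecord,
    SentenceDataset,
    adjudicate,
    highlight_typology,
    interannotator_agreement,
    read_extraction_records,
    train_sentence_classifier,
)

from conftest import FAST_GRIDS


def _rec(i, a, b, referee=None, article="a1"):
    return ExtractionRecord(article_id=article, sentence_index=i,
                            extractor_a=a, extractor_b=b, referee=referee)


class TestAdjudicate:
    @pytest.mark.parametrize(
        "a,b,referee,expected",
        [
            (True, True, None, True),       # both picked -> evidence
            (True, False, False, False),    # referee rejects
            (True, False, True, True),      # referee approves
            (False, False, True, False),    # referee irrelevant when none picked
        ],
    )
    def test_adjudication_rule(self, a, b, referee, expected):
        final = adjudicate([_rec(0, a, b, referee)])
        assert (("a1", 0) in final) is expected

    def test_disagreement_without_referee_names_the_sentence(self):
        with pytest.raises(ValueError, match=r"\('a1', 3\)"):
            adjudicate([_rec(3, True, False)])


class TestAgreement:
    def test_identical_extractions_give_full_agreement(self):
        records = [_rec(i, True, True) for i in range(10)]
        report = interannotator_agreement(records)
        assert report.n_a == report.n_b == report.n_both == report.n_final == 10
        assert report.simple_agreement_pct == 100.0

    def test_direct_count_ratio(self):
        records = [_rec(i, True, True) for i in range(72)]
        records += [_rec(100 + i, True, False, referee=True) for i in range(28)]
        report = interannotator_agreement(records)
        assert report.n_both == 72
        assert report.n_final == 100
        assert report.simple_agreement_pct == pytest.approx(72.00)

    def test_disjoint_extractions_all_approved_give_zero_pct(self):
        records = [_rec(i, True, False, referee=True) for i in range(5)]
        records += [_rec(10 + i, False, True, referee=True) for i in range(5)]
        report = interannotator_agreement(records)
        assert report.n_both == 0
        assert report.simple_agreement_pct == 0.0

    def test_no_positives_reports_not_applicable(self):
        report = interannotator_agreement([_rec(0, False, False)])
        assert report.simple_agreement_pct is None

    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "records.csv"
        path.write_text(
            "article_id,sentence_index,extractor_a,extractor_b,referee\n"
            "a1,0,1,1,\n"
            "a1,2,1,0,1\n"
            "a2,5,0,0,\n"
        )
        records = read_extraction_records(path)
        assert len(records) == 3
        assert adjudicate(records) == {("a1", 0), ("a1", 2)}


class TestSentenceClassifier:
    def test_small_dataset_rejected(self, separable_corpus):
        ds = generate_sentence_dataset(separable_corpus, Criterion.HARM, seed=0)
        tiny = SentenceDataset(items=ds.items[:2] + ds.items[-2:],
                               criterion=Criterion.HARM, seed=0)
        with pytest.raises(ValueError, match="too small"):
            train_sentence_classifier(tiny)

    def test_unbalanced_dataset_rejected(self, separable_corpus):
        ds = generate_sentence_dataset(separable_corpus, Criterion.HARM, seed=0)
        lopsided = SentenceDataset(items=ds.items[:-1],
                                   criterion=Criterion.HARM, seed=0)
        with pytest.raises(ValueError, match="balanced"):
            train_sentence_classifier(lopsided)

    def test_high_holdout_auc_on_separable_sentences(self, separable_corpus,
                                                     harm_sentence_model):
        from newsqual.classify import rank_auc

        holdout = generate_corpus(
            GeneratorConfig(
                n_articles=20,
                satisfied_fraction={Criterion.HARM: 0.5},
                sentences_per_article=(8, 12),
                confounder_rate=0.0,
                seed=77,
            )
        )
        ds = generate_sentence_dataset(holdout, Criterion.HARM, seed=1)
        y = [lbl for _, lbl in ds.items]
        scores = [harm_sentence_model.predict_proba_text(s.text) for s, _ in ds.items]
        assert rank_auc(y, scores) >= 0.9

    def test_seed_determinism(self, separable_corpus):
        ds = generate_sentence_dataset(separable_corpus, Criterion.HARM, seed=2)
        kw = dict(seed=3, n_trials=2, feature_count_grid=(200,), folds=3,
                  grids=FAST_GRIDS)
        m1 = train_sentence_classifier(ds, **kw)
        m2 = train_sentence_classifier(ds, **kw)
        text = ds.items[0][0].text
        assert m1.predict_proba_text(text) == m2.predict_proba_text(text)
        assert m1.spec == m2.spec


class TestHighlightTypology:
    def _positive_article(self, corpus):
        return next(
            a for a in corpus if a.ratings[Criterion.HARM] is Rating.SATISFACTORY
        )

    def test_gold_sentences_rank_first(self, separable_corpus, harm_sentence_model):
        article = self._positive_article(separable_corpus)
        gold = article.gold_evidence[Criterion.HARM]
        k = min(2, len(gold))
        result = highlight_typology(harm_sentence_model, article, Criterion.HARM, k)
        assert len(result.highlights) == k
        assert all(h.sentence.index in gold for h in result.highlights)

    def test_k_zero_is_empty(self, separable_corpus, harm_sentence_model):
        article = self._positive_article(separable_corpus)
        result = highlight_typology(harm_sentence_model, article, Criterion.HARM, 0)
        assert result.highlights == []

    def test_background_only_article_gets_no_highlights(self, harm_sentence_model):
        article = NewsArticle(
            article_id="bg",
            body=(
                "The committee reviewed general procedures. "
                "Observers compared notes across the period. "
                "Many details remained unchanged over several weeks."
            ),
        )
        result = highlight_typology(harm_sentence_model, article, Criterion.HARM, 5)
        assert result.highlights == []

    def test_probability_floor_respected_and_monotone(self, separable_corpus,
                                                      harm_sentence_model):
        article = self._positive_article(separable_corpus)
        result = highlight_typology(harm_sentence_model, article, Criterion.HARM, 10)
        probs = [h.probability for h in result.highlights]
        assert all(p >= 0.5 for p in probs)
        assert probs == sorted(probs, reverse=True)


class TestLexicalVariants:
    def test_typology_beats_hybrid_on_variant_rich_evidence(self):
        """Evidence phrased without the curated keywords is found by the
        sentence classifier but invisible to keyword matching, while
        keyword-bearing confounders mislead the hybrid ranking."""
        from newsqual.classify import ModelSpec, train
        from newsqual.evaluate import highlight_accuracy
        from newsqual.hybrid import highlight_hybrid

        variant_harm = Lexicon(
            criterion=Criterion.HARM,
            evidence_templates=(
                "Regulators issued a safety update urging doctors to watch for the problem.",
                "The medication was linked to bone fractures, joint pain and infections.",
                "Several patients stopped the treatment after developing severe dizziness.",
                "The agency logged reports of fainting and irregular heartbeat among users.",
            ),
            confounder_templates=(
                "The study verified that the drug reduces the risk of fractures by {num} percent.",
                "Daily use lowered the risk of heart attack among older adults.",
            ),
        )
        from newsqual.synth import DEFAULT_LEXICONS

        lexicons = dict(DEFAULT_LEXICONS)
        lexicons[Criterion.HARM] = variant_harm
        cfg = GeneratorConfig(
            n_articles=80,
            satisfied_fraction={Criterion.HARM: 0.5},
            sentences_per_article=(8, 12),
            evidence_per_positive=(1, 3),
            confounder_rate=1.0,
            seed=13,
        )
        corpus = generate_corpus(cfg, lexicons=lexicons)
        train_articles = corpus.articles[:60]
        test_articles = [
            a for a in corpus.articles[60:]
            if a.ratings[Criterion.HARM] is Rating.SATISFACTORY
        ]
        from newsqual.corpus import Corpus

        train_corpus = Corpus(train_articles)
        doc_model = train(ModelSpec("logistic_regression", {"C": 10.0}, 800),
                          train_corpus, Criterion.HARM, seed=0)
        ds = generate_sentence_dataset(train_corpus, Criterion.HARM, seed=1)
        sent_model = train_sentence_classifier(
            ds, seed=2, n_trials=3, feature_count_grid=(500,), folds=3,
            grids=FAST_GRIDS,
        )
        gold = {
            a.article_id: (a.gold_evidence or {}).get(Criterion.HARM, frozenset())
            for a in test_articles
        }
        hybrid_results = [
            highlight_hybrid(doc_model, a, Criterion.HARM, k=1,
                             n_samples=400, seed=4)
            for a in test_articles
        ]
        typology_results = [
            highlight_typology(sent_model, a, Criterion.HARM, k=1)
            for a in test_articles
        ]
        p_hybrid = highlight_accuracy(hybrid_results, gold, k=1)
        p_typology = highlight_accuracy(typology_results, gold, k=1)
        assert p_typology is not None
        assert p_hybrid is None or p_typology >= p_hybrid
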