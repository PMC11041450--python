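import pytest

from newsqual.classify import ModelSpec, train
from newsqual.corpus import Criterion
from newsqual.synth import GeneratorConfig, generate_corpus, generate_sentence_dataset
from newsqual.typology import train_sentence_classifier

BALANCED_FRACTIONS = {
    Criterion.COST: 0.5,
    Criterion.HARM: 0.5,
    Criterion.CONFLICT: 0.5,
}

FAST_GRIDS = {
    "logistic_regression": {"C": [0.1, 1.0, 10.0]},
    "naive_bayes": {"alpha": [0.1, 1.0]},
    "support_vector_machine": {"C": [1.0], "kernel": ["linear"]},
    "random_forest": {
        "n_estimators": [100], "min_samples_split": [2],
        "min_samples_leaf": [1], "max_features": ["sqrt"],
        "max_depth": [None], "bootstrap": [True],
    },
}

LR_SPEC = ModelSpec("logistic_regression", {"C": 10.0}, 800)


@pytest.fixture(scope="session")
def separable_corpus():
    """Balanced, confounder-free corpus: cleanly separable per criterion."""
    cfg = GeneratorConfig(
        n_articles=60,
        satisfied_fraction=dict(BALANCED_FRACTIONS),
        sentences_per_article=(8, 14),
        confounder_rate=0.0,
        seed=11,
    )
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def harm_model(separable_corpus):
    return train(LR_SPEC, separable_corpus, Criterion.HARM, seed=1)


@pytest.fixture(scope="session")
def harm_sentence_model(separable_corpus):
    dataset = generate_sentence_dataset(separable_corpus, Criterion.HARM, seed=3)
    return train_sentence_classifier(
        dataset, seed=4, n_trials=3, feature_count_grid=(300,), folds=3,
        grids=FAST_GRIDS,
    )
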