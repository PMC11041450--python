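"""Perturbation-based local surrogate explanation for text classifiers.

The mechanism: enumerate the distinct in-vocabulary n-grams of one document,
sample binary masks over them (each bit keeps or removes one n-gram type),
re-vectorize each masked variant, query the black-box classifier, weight
each sample by proximity to the intact document through an exponential
kernel on cosine distance in mask space, and fit a weighted ridge regression
of the black-box probability on the mask bits. The signed coefficient of a
feature is its local contribution to the satisfactory prediction.

``exact_surrogate`` solves the same weighted ridge problem over all 2^u
masks of a small document and serves as the enumeration oracle for the
sampled explainer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .classify import TrainedModel
from .corpus import Corpus, Criterion, NewsArticle
from .text import preprocess, vectorize

DEFAULT_KERNEL_WIDTH = 0.75
DEFAULT_RIDGE_PENALTY = 1.0
DEFAULT_N_SAMPLES = 5000


@dataclass(frozen=True)
class MaskSample:
    """One perturbed variant: kept/removed bits, the black-box probability on
    the masked text, and the proximity kernel weight."""

    mask: tuple[int, ...]
    blackbox_prob: float
    kernel_weight: float


@dataclass(frozen=True)
class KeywordWeight:
    ngram: str
    weight: float
    source: str = "lime"  # "lime" (surrogate-derived) or "manual"


@dataclass
class DocExplanation:
    """Ranked keyword attributions for one document."""

    article_id: str
    predicted_prob: float
    keywords: list[KeywordWeight]
    n_samples: int
    kernel_width: float
    seed: int


@dataclass
class GlobalExplanation:
    """Corpus-level top keyword ranking for one criterion classifier."""

    criterion: Criterion
    method: str  # "lime_aggregate" or "model_importance"
    keywords: list[KeywordWeight] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Mask sampling and masking
# ---------------------------------------------------------------------------

def perturb_masks(n_features: int, n_samples: int, seed: int) -> np.ndarray:
    """Binary masks over a document's distinct in-vocabulary n-grams.

    The first mask is all-ones (the intact document); the rest have each bit
    kept independently with probability 0.5."""
    if n_features < 1 or n_samples < 1:
        raise ValueError("n_features and n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    masks = np.ones((n_samples, n_features), dtype=np.int8)
    if n_samples > 1:
        masks[1:] = rng.integers(0, 2, size=(n_samples - 1, n_features), dtype=np.int8)
    return masks


def _doc_feature_columns(model: TrainedModel, article: NewsArticle) -> tuple:
    vec = vectorize(model.tfidf, preprocess(article.body))
    cols = np.sort(vec.indices.copy())
    return vec, cols


def mask_to_vector(doc_vector: sp.csr_matrix, mask: np.ndarray) -> sp.csr_matrix:
    """Zero out the masked n-grams of a document vector and re-normalize to
    unit L2 (a fully masked document becomes the zero vector)."""
    cols = np.sort(doc_vector.indices.copy())
    dense = np.asarray(doc_vector.todense()).ravel()
    vals = dense[cols] * np.asarray(mask, dtype=float)
    norm = float(np.linalg.norm(vals))
    if norm > 0:
        vals = vals / norm
    keep = vals != 0
    return sp.csr_matrix(
        (vals[keep], (np.zeros(keep.sum(), dtype=int), cols[keep])),
        shape=doc_vector.shape,
    )


def _masked_matrix(doc_vector: sp.csr_matrix, masks: np.ndarray) -> sp.csr_matrix:
    """All masked variants stacked into one sparse matrix."""
    cols = np.sort(doc_vector.indices.copy())
    dense = np.asarray(doc_vector.todense()).ravel()
    base = dense[cols]
    weights = masks.astype(float) * base  # (n_samples, u)
    norms = np.linalg.norm(weights, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    weights = weights / norms
    n_samples, u = masks.shape
    rows = np.repeat(np.arange(n_samples), u)
    cols_rep = np.tile(cols, n_samples)
    data = weights.ravel()
    keep = data != 0
    return sp.csr_matrix(
        (data[keep], (rows[keep], cols_rep[keep])),
        shape=(n_samples, doc_vector.shape[1]),
    )


def kernel_weights(masks: np.ndarray, kernel_width: float = DEFAULT_KERNEL_WIDTH) -> np.ndarray:
    """exp(-d^2 / sigma^2) with d the cosine distance between the mask and
    the all-ones mask; the all-zeros mask is at distance 1."""
    masks = np.asarray(masks, dtype=float)
    u = masks.shape[1]
    s = masks.sum(axis=1)
    sim = np.zeros_like(s)
    nonzero = s > 0
    sim[nonzero] = s[nonzero] / np.sqrt(s[nonzero] * u)
    d = 1.0 - sim
    return np.exp(-(d ** 2) / kernel_width ** 2)


# ---------------------------------------------------------------------------
# Weighted ridge surrogate
# ---------------------------------------------------------------------------

def fit_surrogate(
    masks: np.ndarray,
    probs: np.ndarray,
    weights: np.ndarray,
    ridge_penalty: float = DEFAULT_RIDGE_PENALTY,
) -> np.ndarray:
    """Weighted ridge regression of black-box probabilities on mask bits.

    The intercept is unpenalized; the returned array holds the signed
    per-feature coefficients. A feature that never varies across samples gets
    a zero coefficient under any positive penalty (the intercept absorbs it).
    Raises on a degenerate design (all masks identical).
    """
    masks = np.asarray(masks, dtype=float)
    probs = np.asarray(probs, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if masks.shape[0] < 2:
        raise ValueError("need at least 2 mask samples")
    if np.all(masks == masks[0]):
        raise ValueError("degenerate design: all masks identical")
    if not np.any(weights > 0):
        raise ValueError("all kernel weights are zero")
    n, u = masks.shape
    design = np.hstack([np.ones((n, 1)), masks])
    wdesign = design * weights[:, None]
    gram = design.T @ wdesign
    penalty = ridge_penalty * np.eye(u + 1)
    penalty[0, 0] = 0.0  # intercept unpenalized
    rhs = design.T @ (weights * probs)
    coef = np.linalg.solve(gram + penalty, rhs)
    return coef[1:]


def samples_to_arrays(samples: list[MaskSample]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    masks = np.array([s.mask for s in samples], dtype=float)
    probs = np.array([s.blackbox_prob for s in samples], dtype=float)
    weights = np.array([s.kernel_weight for s in samples], dtype=float)
    return masks, probs, weights


# ---------------------------------------------------------------------------
# Document explanation
# ---------------------------------------------------------------------------

def _surrogate_for_masks(
    model: TrainedModel,
    doc_vector: sp.csr_matrix,
    cols: np.ndarray,
    masks: np.ndarray,
    kernel_width: float,
    ridge_penalty: float,
) -> np.ndarray:
    X = _masked_matrix(doc_vector, masks)
    probs = model.predict_matrix(X)
    w = kernel_weights(masks, kernel_width)
    return fit_surrogate(masks, probs, w, ridge_penalty)


def explain_document(
    model: TrainedModel,
    article: NewsArticle,
    n_samples: int = DEFAULT_N_SAMPLES,
    top_m: int | None = 10,
    seed: int = 0,
    kernel_width: float = DEFAULT_KERNEL_WIDTH,
    ridge_penalty: float = DEFAULT_RIDGE_PENALTY,
) -> DocExplanation:
    """Explain one document's prediction with the sampled surrogate.

    Returns the ``top_m`` keywords by absolute weight (all when ``top_m`` is
    None); a positive weight supports the satisfactory class. A document with
    no in-vocabulary n-grams yields an empty keyword list but still reports
    the black-box probability.
    """
    doc_vector, cols = _doc_feature_columns(model, article)
    predicted = float(model.predict_matrix(doc_vector)[0])
    if len(cols) == 0:
        return DocExplanation(
            article_id=article.article_id, predicted_prob=predicted, keywords=[],
            n_samples=n_samples, kernel_width=kernel_width, seed=seed,
        )
    masks = perturb_masks(len(cols), n_samples, seed)
    coefs = _surrogate_for_masks(model, doc_vector, cols, masks,
                                 kernel_width, ridge_penalty)
    keywords = [
        KeywordWeight(ngram=model.tfidf.ngram_for(int(c)), weight=float(w),
                      source="lime")
        for c, w in zip(cols, coefs)
    ]
    keywords.sort(key=lambda kw: (-abs(kw.weight), kw.ngram))
    if top_m is not None:
        keywords = keywords[:top_m]
    return DocExplanation(
        article_id=article.article_id, predicted_prob=predicted,
        keywords=keywords, n_samples=n_samples, kernel_width=kernel_width,
        seed=seed,
    )


def exact_surrogate(
    model: TrainedModel,
    article: NewsArticle,
    max_features: int = 12,
    kernel_width: float = DEFAULT_KERNEL_WIDTH,
    ridge_penalty: float = DEFAULT_RIDGE_PENALTY,
) -> dict[str, float]:
    """Exact surrogate weights by enumerating all 2^u masks of a small
    document; the oracle counterpart of :func:`explain_document`."""
    doc_vector, cols = _doc_feature_columns(model, article)
    u = len(cols)
    if u > max_features:
        raise ValueError(f"document has {u} features > max_features={max_features}")
    if u == 0:
        return {}
    masks = _all_masks(u)
    coefs = _surrogate_for_masks(model, doc_vector, cols, masks,
                                 kernel_width, ridge_penalty)
    return {model.tfidf.ngram_for(int(c)): float(w) for c, w in zip(cols, coefs)}


def _all_masks(u: int) -> np.ndarray:
    """All 2^u binary masks, the all-ones mask first."""
    grid = ((np.arange(2 ** u)[:, None] >> np.arange(u - 1, -1, -1)) & 1).astype(np.int8)
    return grid[::-1].copy()


# ---------------------------------------------------------------------------
# Global ranking
# ---------------------------------------------------------------------------

def global_ranking(
    model: TrainedModel,
    corpus: Corpus,
    criterion: Criterion,
    method: str = "lime_aggregate",
    top: int = 30,
    n_samples: int = 1000,
    seed: int = 0,
) -> GlobalExplanation:
    """Top keyword features of a criterion classifier across the corpus.

    ``lime_aggregate`` averages signed surrogate weights over the documents
    the model predicts satisfactory; ``model_importance`` reads the fitted
    estimator's intrinsic importances. Entries are ranked by magnitude.
    """
    if method not in ("lime_aggregate", "model_importance"):
        raise ValueError(f"unknown method {method!r}")
    if top <= 0:
        return GlobalExplanation(criterion=criterion, method=method, keywords=[])

    if method == "model_importance":
        est = model.estimator
        if hasattr(est, "feature_importances_"):
            imp = np.asarray(est.feature_importances_, dtype=float)
        elif hasattr(est, "coef_"):
            coef = est.coef_
            imp = np.asarray(coef.todense() if sp.issparse(coef) else coef,
                             dtype=float).ravel()
        elif hasattr(est, "feature_log_prob_"):
            flp = est.feature_log_prob_
            imp = np.asarray(flp[1] - flp[0], dtype=float)
        else:
            raise ValueError(
                f"{type(est).__name__} exposes no intrinsic feature importances"
            )
        order = np.argsort(-np.abs(imp), kind="stable")[:top]
        keywords = [
            KeywordWeight(ngram=model.tfidf.ngram_for(int(i)),
                          weight=float(imp[i]), source="lime")
            for i in order
        ]
        return GlobalExplanation(criterion=criterion, method=method, keywords=keywords)

    sums: dict[str, float] = {}
    n_satisfactory = 0
    for i, article in enumerate(corpus):
        if model.predict_proba(article) < 0.5:
            continue
        n_satisfactory += 1
        expl = explain_document(
            model, article, n_samples=n_samples, top_m=None,
            seed=(seed + i) % 2**31,
        )
        for kw in expl.keywords:
            sums[kw.ngram] = sums.get(kw.ngram, 0.0) + kw.weight
    if n_satisfactory == 0:
        raise ValueError("no documents predicted satisfactory; cannot aggregate")
    entries = [
        KeywordWeight(ngram=g, weight=s / n_satisfactory, source="lime")
        for g, s in sums.items()
    ]
    entries.sort(key=lambda kw: (-abs(kw.weight), kw.ngram))
    return GlobalExplanation(criterion=criterion, method=method,
                             keywords=entries[:top])
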