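"""Typology approach: evidence-sentence dataset construction, agreement
statistics, a sentence-level evidence classifier, and probability-ranked
highlighting.

Evidence sentences are collected by two independent extractors; sentences
picked by both are evidence, and a third referee resolves one-sided picks.
A balanced dataset (evidence vs. an equal random sample of non-evidence
sentences) then trains a sentence classifier through the same TF-IDF +
model-family machinery used at the document level.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .classify import SearchResult, TrainedModel, random_search_xy, train_xy
from .corpus import Criterion, NewsArticle, Sentence

# ---------------------------------------------------------------------------
# Extraction records and adjudication
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtractionRecord:
    """One sentence's extraction outcome from the two-extractor protocol."""

    article_id: str
    sentence_index: int
    extractor_a: bool
    extractor_b: bool
    referee: Optional[bool] = None

    @property
    def final(self) -> bool:
        if self.extractor_a and self.extractor_b:
            return True
        if self.extractor_a != self.extractor_b:
            if self.referee is None:
                raise ValueError(
                    f"sentence ({self.article_id}, {self.sentence_index}): "
                    "extractors disagree and no referee decision is present"
                )
            return bool(self.referee)
        return False


def adjudicate(records: Sequence[ExtractionRecord]) -> set[tuple[str, int]]:
    """Final positive set: both extractors agree, or the referee approves a
    one-sided pick. Raises if a disagreement lacks a referee decision."""
    missing = [
        (r.article_id, r.sentence_index)
        for r in records
        if r.extractor_a != r.extractor_b and r.referee is None
    ]
    if missing:
        raise ValueError(f"referee decision missing for sentences: {missing}")
    return {(r.article_id, r.sentence_index) for r in records if r.final}


@dataclass(frozen=True)
class AgreementReport:
    """Interannotator agreement counts for the extraction protocol.

    ``simple_agreement_pct`` is 100 x n_both / n_final: the share of the
    adjudicated positives that both extractors picked independently. ``None``
    when no positives exist.
    """

    n_a: int
    n_b: int
    n_both: int
    n_final: int
    simple_agreement_pct: Optional[float]


def interannotator_agreement(records: Sequence[ExtractionRecord]) -> AgreementReport:
    final = adjudicate(records)
    n_a = sum(r.extractor_a for r in records)
    n_b = sum(r.extractor_b for r in records)
    n_both = sum(r.extractor_a and r.extractor_b for r in records)
    n_final = len(final)
    pct = 100.0 * n_both / n_final if n_final else None
    return AgreementReport(n_a=n_a, n_b=n_b, n_both=n_both, n_final=n_final,
                           simple_agreement_pct=pct)


def read_extraction_records(path: str | Path) -> list[ExtractionRecord]:
    """Read extraction records from a CSV with columns article_id,
    sentence_index, extractor_a, extractor_b, referee (blank = no referee)."""

    def as_bool(value: str) -> bool:
        return value.strip().lower() in {"1", "true", "yes"}

    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            ref = row.get("referee", "")
            records.append(
                ExtractionRecord(
                    article_id=row["article_id"],
                    sentence_index=int(row["sentence_index"]),
                    extractor_a=as_bool(row["extractor_a"]),
                    extractor_b=as_bool(row["extractor_b"]),
                    referee=as_bool(ref) if ref and ref.strip() else None,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Sentence dataset and classifier
# ---------------------------------------------------------------------------

@dataclass
class SentenceDataset:
    """Balanced sentence-level dataset; label 1 = evidence, 0 = non-evidence."""

    items: list[tuple[Sentence, int]]
    criterion: Criterion
    seed: int

    def __len__(self) -> int:
        return len(self.items)

    @property
    def balanced(self) -> bool:
        pos = sum(lbl for _, lbl in self.items)
        return pos * 2 == len(self.items)


def train_sentence_classifier(
    dataset: SentenceDataset,
    seed: int = 0,
    n_trials: int = 8,
    feature_count_grid: Sequence[int] = (500, 1000),
    folds: int = 5,
    grids: Optional[dict] = None,
    return_search: bool = False,
) -> TrainedModel | tuple[TrainedModel, SearchResult]:
    """Random-search and fit an evidence-sentence classifier.

    Reuses the document-level machinery (TF-IDF on sentences, the four model
    families, random search scored by stratified k-fold mean AUC). Requires a
    balanced dataset of at least 20 sentences.
    """
    if len(dataset) < 20:
        raise ValueError(f"sentence dataset too small ({len(dataset)} < 20)")
    if not dataset.balanced:
        raise ValueError("sentence dataset must be exactly class-balanced")
    texts = [s.text for s, _ in dataset.items]
    labels = [lbl for _, lbl in dataset.items]
    search = random_search_xy(
        texts, labels, n_trials=n_trials,
        feature_count_grid=feature_count_grid, seed=seed, folds=folds,
        grids=grids,
    )
    model = train_xy(search.best_spec, texts, labels, seed=seed)
    return (model, search) if return_search else model


def highlight_typology(
    sentence_model: TrainedModel,
    article: NewsArticle,
    criterion: Criterion,
    k: int,
    probability_floor: float = 0.5,
):
    """Rank the article's sentences by evidence probability and keep the top
    ``k`` whose probability clears ``probability_floor`` (default 0.5).

    Ties break toward the earlier sentence. Returns a HighlightResult; fewer
    than ``k`` highlights when fewer sentences qualify.
    """
    from .hybrid import HighlightEntry, HighlightResult  # avoid import cycle

    scored = []
    for sentence in article.sentences():
        prob = sentence_model.predict_proba_text(sentence.text)
        if prob >= probability_floor:
            scored.append((prob, sentence))
    scored.sort(key=lambda t: (-t[0], t[1].index))
    highlights = [
        HighlightEntry(
            sentence=s, tier="typology", score=float(p),
            matched=(), probability=float(p),
        )
        for p, s in scored[: max(k, 0)]
    ]
    return HighlightResult(
        article_id=article.article_id,
        criterion=criterion,
        approach="typology",
        k=k,
        highlights=highlights,
    )
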