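"""Hybrid highlighting: surrogate keywords merged with curated keyword lists.

Curated (manual) keywords always outrank surrogate-derived ones: sentences
are scored lexicographically by (tier, magnitude), where the manual tier
strictly dominates the surrogate tier regardless of numeric weight. Within a
tier, the magnitude sums a fixed bonus of 1.0 per manual phrase occurrence
plus the absolute surrogate weights of matched n-grams. Ties break toward
the earlier sentence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .classify import TrainedModel
from .corpus import Criterion, NewsArticle, Sentence
from .explain import (
    DEFAULT_KERNEL_WIDTH,
    DEFAULT_N_SAMPLES,
    DEFAULT_RIDGE_PENALTY,
    DocExplanation,
    KeywordWeight,
    explain_document,
)
from .text import preprocess

#: Curated per-criterion keyword phrases (unigrams and bigrams).
MANUAL_KEYWORDS: dict[Criterion, tuple[str, ...]] = {
    Criterion.COST: ("price", "cost", "charge", "insurance", "pay"),
    Criterion.HARM: ("side effect", "adverse reaction", "adverse event",
                     "complication", "risk"),
    Criterion.CONFLICT: ("fund", "sponsor", "grant", "spokesman",
                         "professor", "director"),
}

MANUAL_BONUS = 1.0  # score contribution per manual phrase occurrence


@dataclass(frozen=True)
class ManualKeywordSet:
    criterion: Criterion
    keywords: tuple[str, ...]


def default_manual_keywords(criterion: Criterion) -> ManualKeywordSet:
    return ManualKeywordSet(criterion=criterion, keywords=MANUAL_KEYWORDS[criterion])


@dataclass
class MergedKeywords:
    """Keyword entries with a source tier; manual strictly above surrogate."""

    entries: list[KeywordWeight] = field(default_factory=list)

    def by_source(self, source: str) -> list[KeywordWeight]:
        return [e for e in self.entries if e.source == source]


def _normalize_phrase(phrase: str) -> str:
    return " ".join(preprocess(phrase).tokens)


def merge_keywords(expl: DocExplanation, manual: ManualKeywordSet) -> MergedKeywords:
    """Combine positive surrogate keywords with the curated list.

    Only positive-weight surrogate entries (those supporting a satisfactory
    prediction) participate. Phrases present in both lists collapse onto the
    manual tier."""
    manual_entries: list[KeywordWeight] = []
    manual_norm: set[str] = set()
    for phrase in manual.keywords:
        norm = _normalize_phrase(phrase)
        if norm and norm not in manual_norm:
            manual_norm.add(norm)
            manual_entries.append(KeywordWeight(ngram=norm, weight=0.0, source="manual"))
    lime_entries = [
        kw for kw in expl.keywords
        if kw.source == "lime" and kw.weight > 0 and kw.ngram not in manual_norm
    ]
    lime_entries.sort(key=lambda kw: (-kw.weight, kw.ngram))
    return MergedKeywords(entries=manual_entries + lime_entries)


def _count_phrase(tokens: Sequence[str], phrase_tokens: Sequence[str]) -> int:
    n, m = len(tokens), len(phrase_tokens)
    if m == 0 or m > n:
        return 0
    return sum(
        1 for i in range(n - m + 1) if tuple(tokens[i:i + m]) == tuple(phrase_tokens)
    )


def match_keywords(
    sentence: Sentence, merged: MergedKeywords
) -> list[tuple[KeywordWeight, int]]:
    """Entries matching the sentence, with occurrence counts.

    Matching is on the normalized token sequence, so inflected forms match
    ("risks" matches "risk"); multiword phrases must appear as contiguous
    normalized token runs."""
    tokens = preprocess(sentence.text).tokens
    matched = []
    for entry in merged.entries:
        count = _count_phrase(tokens, entry.ngram.split(" "))
        if count:
            matched.append((entry, count))
    return matched


def score_sentence(matched: Sequence[tuple[KeywordWeight, int]]) -> tuple[int, float]:
    """Lexicographic (tier, magnitude) score.

    tier 2 = at least one manual match, 1 = surrogate matches only,
    0 = no matches (never highlighted). The magnitude adds MANUAL_BONUS per
    manual occurrence plus |weight| per surrogate occurrence."""
    manual_occ = sum(c for e, c in matched if e.source == "manual")
    lime_mag = sum(abs(e.weight) * c for e, c in matched if e.source == "lime")
    if manual_occ:
        return 2, MANUAL_BONUS * manual_occ + lime_mag
    if lime_mag > 0:
        return 1, lime_mag
    return 0, 0.0


@dataclass(frozen=True)
class HighlightEntry:
    sentence: Sentence
    tier: str  # "manual", "lime", or "typology"
    score: float
    matched: tuple[str, ...] = ()
    probability: Optional[float] = None


@dataclass
class HighlightResult:
    """Ranked sentence highlights for one article and criterion."""

    article_id: str
    criterion: Criterion
    approach: str  # "hybrid" or "typology"
    k: int
    highlights: list[HighlightEntry] = field(default_factory=list)

    def truncated(self, k: int) -> "HighlightResult":
        return HighlightResult(
            article_id=self.article_id, criterion=self.criterion,
            approach=self.approach, k=k, highlights=self.highlights[:max(k, 0)],
        )

    def to_dict(self) -> dict:
        return {
            "article_id": self.article_id,
            "criterion": self.criterion.value,
            "approach": self.approach,
            "k": self.k,
            "highlights": [
                {
                    "index": h.sentence.index,
                    "char_start": h.sentence.char_start,
                    "char_end": h.sentence.char_end,
                    "text": h.sentence.text,
                    "tier": h.tier,
                    "score": round(h.score, 12),
                    "matched": list(h.matched),
                    "probability": (
                        None if h.probability is None else round(h.probability, 12)
                    ),
                }
                for h in self.highlights
            ],
        }


def highlight_hybrid(
    model: TrainedModel,
    article: NewsArticle,
    criterion: Criterion,
    k: int,
    manual: Optional[ManualKeywordSet] = None,
    n_samples: int = DEFAULT_N_SAMPLES,
    top_m: int | None = 20,
    seed: int = 0,
    kernel_width: float = DEFAULT_KERNEL_WIDTH,
    ridge_penalty: float = DEFAULT_RIDGE_PENALTY,
    explanation: Optional[DocExplanation] = None,
) -> HighlightResult:
    """Full hybrid pipeline: explain the document, merge keywords, match and
    score every sentence, and return the top ``k`` scoring sentences.

    Manual-tier sentences always precede surrogate-tier sentences; unmatched
    sentences are never highlighted, so fewer than ``k`` entries may return.
    A precomputed ``explanation`` may be supplied to skip the surrogate run.
    """
    manual = manual or default_manual_keywords(criterion)
    if explanation is None:
        explanation = explain_document(
            model, article, n_samples=n_samples, top_m=top_m, seed=seed,
            kernel_width=kernel_width, ridge_penalty=ridge_penalty,
        )
    merged = merge_keywords(explanation, manual)
    scored: list[tuple[int, float, Sentence, tuple[str, ...]]] = []
    for sentence in article.sentences():
        matched = match_keywords(sentence, merged)
        tier, magnitude = score_sentence(matched)
        if tier > 0:
            phrases = tuple(e.ngram for e, _ in matched)
            scored.append((tier, magnitude, sentence, phrases))
    scored.sort(key=lambda t: (-t[0], -t[1], t[2].index))
    highlights = [
        HighlightEntry(
            sentence=s, tier="manual" if tier == 2 else "lime",
            score=mag, matched=phrases,
        )
        for tier, mag, s, phrases in scored[: max(k, 0)]
    ]
    return HighlightResult(
        article_id=article.article_id, criterion=criterion,
        approach="hybrid", k=k, highlights=highlights,
    )
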