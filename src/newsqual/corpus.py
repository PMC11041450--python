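"""Domain model for criteria-rated health news.

A corpus is an ordered collection of news articles. Each article carries a
plain-text body, a source type (news story vs. press release), per-criterion
quality ratings, and — when known — the indices of the sentences that justify
a "satisfactory" rating (gold evidence).

Corpora are stored as JSONL: one UTF-8 JSON object per line with the fields
``article_id``, ``source_type``, ``title``, ``body``, ``ratings`` and
optionally ``gold_evidence``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional


class Criterion(str, Enum):
    """A quality-assessment criterion applied to a health news article.

    - ``cost``: does the article discuss the costs of the intervention?
    - ``harm``: does it explain or quantify the harms of the intervention?
    - ``conflict``: does it identify conflicts of interest?
    """

    COST = "cost"
    HARM = "harm"
    CONFLICT = "conflict"


class Rating(str, Enum):
    """Outcome of evaluating one criterion on one article."""

    SATISFACTORY = "satisfactory"
    UNSATISFACTORY = "unsatisfactory"
    NOT_APPLICABLE = "not_applicable"


def binarize_label(rating: Rating) -> int:
    """Collapse the three-valued rating onto a binary label.

    ``satisfactory`` maps to 1; both ``unsatisfactory`` and ``not_applicable``
    map to 0, so the classification task is "satisfactory vs. the rest".
    """
    return 1 if rating is Rating.SATISFACTORY else 0


@dataclass(frozen=True)
class Sentence:
    """One sentence of an article body, with half-open character offsets.

    ``text == body[char_start:char_end]`` always holds; offsets are 0-based.
    """

    article_id: str
    index: int
    char_start: int
    char_end: int
    text: str


@dataclass
class NewsArticle:
    article_id: str
    body: str
    source_type: str = "story"
    title: str = ""
    ratings: dict[Criterion, Rating] = field(default_factory=dict)
    gold_evidence: Optional[dict[Criterion, frozenset[int]]] = None

    def sentences(self) -> list[Sentence]:
        return split_sentences(self.body, article_id=self.article_id)


@dataclass
class Corpus:
    articles: list[NewsArticle] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [a.article_id for a in self.articles]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate article_id in corpus")

    def __len__(self) -> int:
        return len(self.articles)

    def __iter__(self) -> Iterator[NewsArticle]:
        return iter(self.articles)

    def __getitem__(self, article_id: str) -> NewsArticle:
        for a in self.articles:
            if a.article_id == article_id:
                return a
        raise KeyError(article_id)


class CorpusFormatError(ValueError):
    """Raised when a corpus file violates the record contract."""


# ---------------------------------------------------------------------------
# Sentence splitting
# ---------------------------------------------------------------------------

#: Abbreviations whose trailing period never ends a sentence.
ABBREVIATIONS = (
    "Dr.", "Mr.", "Mrs.", "Ms.", "St.", "U.S.", "e.g.", "i.e.",
    "Fig.", "No.", "vs.",
)

_TERMINAL = re.compile(r"[.?!]+")


def _is_abbreviation(body: str, end: int) -> bool:
    # end points just past a single '.' — check the word it terminates.
    prefix = body[:end]
    return any(prefix.endswith(abbr) for abbr in ABBREVIATIONS)


def split_sentences(body: str, article_id: str = "") -> list[Sentence]:
    """Split a body into sentences with exact character offsets.

    Rule-based and fully deterministic: a run of ``.?!`` ends a sentence when
    it is followed by whitespace and an upper-case letter (or an opening
    quote before one), unless the period closes a known abbreviation. Text
    after the last terminal run forms a final sentence. A whitespace-only
    body yields an empty list.
    """
    boundaries: list[int] = []
    for m in _TERMINAL.finditer(body):
        end = m.end()
        if end >= len(body):
            boundaries.append(end)
            continue
        # require whitespace then a capital (possibly behind a quote)
        j = end
        if not body[j].isspace():
            continue
        while j < len(body) and body[j].isspace():
            j += 1
        if j >= len(body):
            boundaries.append(end)
            continue
        nxt = body[j]
        if nxt in "\"'“‘(":
            k = j + 1
            nxt = body[k] if k < len(body) else ""
        if not (nxt[:1].isupper() or nxt[:1].isdigit()):
            continue
        if m.group() == "." and _is_abbreviation(body, end):
            continue
        boundaries.append(end)
    if not boundaries or boundaries[-1] < len(body.rstrip()):
        boundaries.append(len(body))

    sentences: list[Sentence] = []
    cursor = 0
    for end in boundaries:
        start = cursor
        while start < end and body[start].isspace():
            start += 1
        trimmed_end = end
        while trimmed_end > start and body[trimmed_end - 1].isspace():
            trimmed_end -= 1
        if trimmed_end > start:
            sentences.append(
                Sentence(
                    article_id=article_id,
                    index=len(sentences),
                    char_start=start,
                    char_end=trimmed_end,
                    text=body[start:trimmed_end],
                )
            )
        cursor = end
    return sentences


# ---------------------------------------------------------------------------
# JSONL corpus I/O
# ---------------------------------------------------------------------------

_REQUIRED_FIELDS = ("article_id", "body", "ratings")


def _article_to_record(article: NewsArticle) -> dict:
    rec: dict = {
        "article_id": article.article_id,
        "source_type": article.source_type,
        "title": article.title,
        "body": article.body,
        "ratings": {c.value: r.value for c, r in article.ratings.items()},
    }
    if article.gold_evidence is not None:
        rec["gold_evidence"] = {
            c.value: sorted(idx) for c, idx in article.gold_evidence.items()
        }
    return rec


def _record_to_article(rec: dict, lineno: int) -> NewsArticle:
    for f in _REQUIRED_FIELDS:
        if f not in rec:
            raise CorpusFormatError(f"line {lineno}: missing required field {f!r}")
    if not rec["body"]:
        raise CorpusFormatError(f"line {lineno}: empty body")
    try:
        ratings = {Criterion(c): Rating(r) for c, r in rec["ratings"].items()}
    except ValueError as exc:
        raise CorpusFormatError(f"line {lineno}: {exc}") from exc
    gold = None
    if rec.get("gold_evidence") is not None:
        gold = {
            Criterion(c): frozenset(int(i) for i in idx)
            for c, idx in rec["gold_evidence"].items()
        }
    article = NewsArticle(
        article_id=str(rec["article_id"]),
        source_type=rec.get("source_type", "story"),
        title=rec.get("title", ""),
        body=rec["body"],
        ratings=ratings,
        gold_evidence=gold,
    )
    if gold:
        n = len(article.sentences())
        for c, idx in gold.items():
            bad = [i for i in idx if not (0 <= i < n)]
            if bad:
                raise CorpusFormatError(
                    f"line {lineno}: gold_evidence[{c.value}] indices {bad} "
                    f"out of range for {n} sentences"
                )
    return article


def load_corpus(path: str | Path) -> Corpus:
    """Read a JSONL corpus file. Record order is preserved.

    A record missing a required field raises :class:`CorpusFormatError`
    naming the line; a duplicate ``article_id`` is a hard failure.
    """
    articles: list[NewsArticle] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: invalid JSON: {exc}") from exc
            article = _record_to_article(rec, lineno)
            if article.article_id in seen:
                raise CorpusFormatError(
                    f"line {lineno}: duplicate article_id {article.article_id!r}"
                )
            seen.add(article.article_id)
            articles.append(article)
    return Corpus(articles)


def write_corpus(corpus: Corpus | Iterable[NewsArticle], path: str | Path) -> None:
    """Write a corpus as JSONL with sorted keys (byte-stable for a fixed corpus)."""
    articles = corpus.articles if isinstance(corpus, Corpus) else list(corpus)
    with open(path, "w", encoding="utf-8") as fh:
        for article in articles:
            fh.write(
                json.dumps(_article_to_record(article), sort_keys=True, ensure_ascii=False)
            )
            fh.write("\n")
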