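"""Highlighting accuracy as a function of window size, and threshold-based
window selection.

Accuracy at a window size k is pooled (micro): 100 x (highlighted sentences
that are gold evidence) / (all highlighted sentences), over every test
article, with each article contributing at most its top-k highlights. The
selected window is the largest k whose accuracy stays at or above the
threshold for every j <= k (prefix rule, inclusive comparison).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

from .corpus import Criterion, NewsArticle
from .hybrid import HighlightResult

GoldEvidence = Mapping[str, frozenset[int] | set[int]]


@dataclass
class AccuracyCurve:
    """Pooled highlighting accuracy (percent) at k = 1..K_max."""

    approach: str
    criterion: Criterion
    accuracy_at_k: list[Optional[float]]
    n_test_docs: int = 0

    @property
    def k_max(self) -> int:
        return len(self.accuracy_at_k)


@dataclass(frozen=True)
class WindowSelection:
    threshold_pct: float
    window: int


def highlight_accuracy(
    results: Sequence[HighlightResult],
    gold: GoldEvidence,
    k: int,
) -> Optional[float]:
    """Percent of highlighted sentences (top-k per article, pooled) that are
    gold evidence. ``None`` when nothing is highlighted at all."""
    total = 0
    correct = 0
    for result in results:
        gold_idx = gold.get(result.article_id, frozenset())
        for entry in result.highlights[: max(k, 0)]:
            total += 1
            if entry.sentence.index in gold_idx:
                correct += 1
    if total == 0:
        return None
    return 100.0 * correct / total


def accuracy_curve(
    approach: str,
    criterion: Criterion,
    highlighter: Callable[[NewsArticle, int], HighlightResult],
    articles: Sequence[NewsArticle],
    gold: GoldEvidence,
    k_max: int = 6,
) -> AccuracyCurve:
    """Accuracy spectrum for k = 1..k_max on a fixed test set.

    The highlighter is invoked once per article at ``k_max``; smaller windows
    are prefixes of that ranking."""
    if not articles:
        raise ValueError("empty test set")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    results = [highlighter(a, k_max) for a in articles]
    curve = [highlight_accuracy(results, gold, k) for k in range(1, k_max + 1)]
    return AccuracyCurve(
        approach=approach, criterion=criterion,
        accuracy_at_k=curve, n_test_docs=len(articles),
    )


def select_window(curve: AccuracyCurve, threshold_pct: float = 75.0) -> WindowSelection:
    """Largest k such that accuracy_at_j >= threshold for every j <= k.

    The comparison is inclusive; an undefined accuracy (no highlights) stops
    the prefix. Window 0 when accuracy at k=1 already misses the threshold."""
    window = 0
    for acc in curve.accuracy_at_k:
        if acc is None or acc < threshold_pct:
            break
        window += 1
    return WindowSelection(threshold_pct=threshold_pct, window=window)


@dataclass
class ComparisonRow:
    k: int
    typology: Optional[float]
    hybrid: Optional[float]
    winner: Optional[str]
    typology_passes: bool
    hybrid_passes: bool


@dataclass
class ComparisonReport:
    criterion: Criterion
    threshold_pct: float
    rows: list[ComparisonRow] = field(default_factory=list)


def compare_approaches(
    hybrid_curve: AccuracyCurve,
    typology_curve: AccuracyCurve,
    threshold_pct: float = 75.0,
) -> ComparisonReport:
    """Side-by-side per-k comparison with winner flags and threshold marks."""
    if hybrid_curve.k_max != typology_curve.k_max:
        raise ValueError("curves have mismatched K_max")
    rows = []
    for i, (h, t) in enumerate(
        zip(hybrid_curve.accuracy_at_k, typology_curve.accuracy_at_k), start=1
    ):
        if h is None or t is None or h == t:
            winner = None
        else:
            winner = "hybrid" if h > t else "typology"
        rows.append(
            ComparisonRow(
                k=i, typology=t, hybrid=h, winner=winner,
                typology_passes=t is not None and t >= threshold_pct,
                hybrid_passes=h is not None and h >= threshold_pct,
            )
        )
    return ComparisonReport(
        criterion=hybrid_curve.criterion, threshold_pct=threshold_pct, rows=rows
    )


# ---------------------------------------------------------------------------
# Serialization and the published reference table
# ---------------------------------------------------------------------------

def curve_to_csv(curve: AccuracyCurve, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["k", "accuracy_pct"])
        for i, acc in enumerate(curve.accuracy_at_k, start=1):
            writer.writerow([i, "" if acc is None else f"{acc:.6f}"])


def curve_from_csv(path: str | Path, approach: str, criterion: Criterion) -> AccuracyCurve:
    values: list[Optional[float]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            cell = row["accuracy_pct"]
            values.append(float(cell) if cell else None)
    return AccuracyCurve(approach=approach, criterion=criterion, accuracy_at_k=values)


def load_published_accuracy() -> dict[Criterion, dict[str, AccuracyCurve]]:
    """Published per-criterion accuracy spectra (percent, k = 1..6) for both
    approaches, shipped as a package fixture."""
    payload = json.loads(
        resources.files("newsqual.data")
        .joinpath("published_accuracy_table.json")
        .read_text(encoding="utf-8")
    )
    out: dict[Criterion, dict[str, AccuracyCurve]] = {}
    for crit_name, approaches in payload.items():
        crit = Criterion(crit_name)
        out[crit] = {
            approach: AccuracyCurve(
                approach=approach, criterion=crit,
                accuracy_at_k=[float(v) for v in values],
            )
            for approach, values in approaches.items()
        }
    return out
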