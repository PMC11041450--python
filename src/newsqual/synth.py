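"""Seeded synthetic corpus generator.

Emulates the statistical structure of a criteria-rated health news corpus:
bodies of 10-60 sentences; a minority of articles "satisfactory" per
criterion (defaults mirror the observed class ratios — roughly 25% for cost,
45% for harm, and 2% for conflict); 1-6 planted evidence sentences per
satisfactory article instantiated from criterion lexicons; confounder
sentences that share criterion keywords without being evidence
(benefit-phrased "reduces the risk of ..." sentences for harm, stock-price
sentences for cost); and background sentences drawn from a closed neutral
vocabulary. Gold evidence indices are recorded per criterion.

Identical seeds produce byte-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus, Criterion, NewsArticle, Rating, split_sentences
from .text import STOP_WORDS, preprocess
from .typology import SentenceDataset

# ---------------------------------------------------------------------------
# Lexicons: sentence templates per criterion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Lexicon:
    """Evidence and confounder sentence templates for one criterion.

    Every evidence template contains at least one of the criterion's manual
    keywords; confounder templates share a keyword but are not evidence.
    """

    criterion: Criterion
    evidence_templates: tuple[str, ...]
    confounder_templates: tuple[str, ...]


DEFAULT_LEXICONS: dict[Criterion, Lexicon] = {
    Criterion.COST: Lexicon(
        criterion=Criterion.COST,
        evidence_templates=(
            "The treatment costs about {num} dollars per month and many insurance plans refuse to pay.",
            "Patients can expect to pay a price of {num} dollars for the full course.",
            "The out of pocket charge is {num} dollars, although insurance may cover part of the cost.",
            "Medicare will pay for the procedure, which carries a cost of roughly {num} dollars.",
            "An insurance copay of {num} dollars applies, and the list price keeps rising every year.",
        ),
        confounder_templates=(
            "Shares of {company} jumped {num} percent as the stock price climbed after the announcement.",
            "The company's stock price fell sharply, wiping out recent gains for investors in {company}.",
        ),
    ),
    Criterion.HARM: Lexicon(
        criterion=Criterion.HARM,
        evidence_templates=(
            "Common side effects included nausea, headache and dizziness among trial participants.",
            "The drug carries a risk of serious complications such as internal bleeding.",
            "About {num} percent of patients reported an adverse reaction during the study.",
            "Investigators recorded {num} adverse events, including two cases of severe infection.",
            "Doctors warned of complications and a small risk of permanent nerve damage.",
        ),
        confounder_templates=(
            "The study verified that long term use of the drug reduces the risk of fractures by {num} percent.",
            "Taking the supplement daily lowered the risk of heart attack among participants by {num} percent.",
        ),
    ),
    Criterion.CONFLICT: Lexicon(
        criterion=Criterion.CONFLICT,
        evidence_templates=(
            "The study was funded by a grant from the manufacturer, a company spokesman said.",
            "Professor {name}, who led the trial, is a paid director of the company that sponsors the work.",
            "The research was supported by a sponsor with a direct financial stake in the outcome.",
            "A spokesman confirmed that the fund behind the research is controlled by the drug maker.",
            "The lead author received a grant and consulting fees from {company}, which sponsors similar trials.",
        ),
        confounder_templates=(
            "A university professor not involved in the research praised the careful design of the work.",
        ),
    ),
}

#: Orange-wire vocabulary for slot filling; closed lists, no external data.
_COMPANIES = ("Acme Health", "Novara Labs", "Stellex Pharma", "Briarwood Biotech")
_NAMES = ("Keller", "Alvarez", "Okafor", "Lindqvist")

_BACKGROUND_TEMPLATES = (
    "The {w0} of the {w1} was discussed during the {w2} meeting.",
    "Researchers described the {w0} and the {w1} in the new report.",
    "Many participants in the {w0} group noticed the {w1} over several weeks.",
    "The {w0} remained stable while the {w1} changed slowly over time.",
    "Observers compared the {w0} with the {w1} across the {w2} period.",
)


def _background_vocabulary(
    size: int, lexicons: dict[Criterion, Lexicon] | None = None
) -> tuple[str, ...]:
    """Deterministic pseudo-words (CVCV syllable pairs) disjoint from stop
    words and from every criterion keyword under normalization."""
    syllables = [c + v for c in "bdfglmnprstvz" for v in "aeiou"]
    banned = set(STOP_WORDS)
    for lex in (lexicons or DEFAULT_LEXICONS).values():
        for tpl in lex.evidence_templates + lex.confounder_templates:
            banned.update(preprocess(tpl).tokens)
    words: list[str] = []
    for s1 in syllables:
        for s2 in syllables:
            w = s1 + s2
            if w in banned or preprocess(w).tokens and preprocess(w).tokens[0] in banned:
                continue
            words.append(w)
            if len(words) == size:
                return tuple(words)
    raise ValueError(f"cannot build a background vocabulary of size {size}")


# ---------------------------------------------------------------------------
# Generator configuration
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    n_articles: int = 100
    satisfied_fraction: dict[Criterion, float] = field(
        default_factory=lambda: {
            Criterion.COST: 0.25,
            Criterion.HARM: 0.45,
            Criterion.CONFLICT: 0.02,
        }
    )
    sentences_per_article: tuple[int, int] = (10, 60)
    evidence_per_positive: tuple[int, int] = (1, 6)
    confounder_rate: float = 0.3
    background_vocab_size: int = 120
    not_applicable_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        smin, smax = self.sentences_per_article
        emin, emax = self.evidence_per_positive
        if self.n_articles <= 0:
            raise ValueError("n_articles must be positive")
        if not (0 < smin <= smax):
            raise ValueError("invalid sentences_per_article range")
        if not (0 < emin <= emax <= 6):
            raise ValueError("invalid evidence_per_positive range (max 6)")
        for c, f in self.satisfied_fraction.items():
            if not (0.0 < f < 1.0):
                raise ValueError(f"satisfied_fraction[{c.value}] must be in (0,1)")
        if emin > smax:
            raise ValueError(
                "infeasible config: minimum evidence count exceeds the "
                "maximum sentence count per article"
            )
        if not (0.0 <= self.confounder_rate <= 1.0):
            raise ValueError("confounder_rate must be a probability")


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

_CRITERIA = (Criterion.COST, Criterion.HARM, Criterion.CONFLICT)


def _fill(template: str, rng: np.random.Generator, vocab: tuple[str, ...]) -> str:
    out = template
    while "{num}" in out:
        out = out.replace("{num}", str(int(rng.integers(2, 96))), 1)
    while "{company}" in out:
        out = out.replace("{company}", _COMPANIES[int(rng.integers(len(_COMPANIES)))], 1)
    while "{name}" in out:
        out = out.replace("{name}", _NAMES[int(rng.integers(len(_NAMES)))], 1)
    for slot in ("{w0}", "{w1}", "{w2}"):
        while slot in out:
            out = out.replace(slot, vocab[int(rng.integers(len(vocab)))], 1)
    return out


def generate_corpus(
    config: GeneratorConfig,
    lexicons: dict[Criterion, Lexicon] | None = None,
) -> Corpus:
    """Generate a corpus with gold evidence populated.

    Per-article criterion labels are sampled independently per criterion.
    Satisfactory articles carry between ``evidence_per_positive`` min and max
    planted evidence sentences for that criterion (clipped only when several
    simultaneously satisfied criteria compete for room); unsatisfactory
    articles carry none. Confounder sentences are inserted per criterion with
    probability ``confounder_rate`` and are never gold.
    """
    config.validate()
    lexicons = lexicons or DEFAULT_LEXICONS
    rng = np.random.default_rng(config.seed)
    vocab = _background_vocabulary(config.background_vocab_size, lexicons)
    smin, smax = config.sentences_per_article
    emin, emax = config.evidence_per_positive

    articles: list[NewsArticle] = []
    for n in range(config.n_articles):
        n_sent = int(rng.integers(smin, smax + 1))
        ratings: dict[Criterion, Rating] = {}
        satisfied: list[Criterion] = []
        for crit in _CRITERIA:
            frac = config.satisfied_fraction.get(crit)
            if frac is None:
                continue
            if rng.random() < frac:
                ratings[crit] = Rating.SATISFACTORY
                satisfied.append(crit)
            elif rng.random() < config.not_applicable_rate:
                ratings[crit] = Rating.NOT_APPLICABLE
            else:
                ratings[crit] = Rating.UNSATISFACTORY

        required = emin * len(satisfied)
        if n_sent < required:
            raise ValueError(
                f"infeasible config: article needs {required} evidence "
                f"sentences but has only {n_sent} sentences"
            )

        # (kind, criterion, text) sentence plan
        plan: list[tuple[str, Criterion | None, str]] = []
        remaining_min = required
        for crit in satisfied:
            remaining_min -= emin
            capacity = n_sent - len(plan) - remaining_min
            count = min(int(rng.integers(emin, emax + 1)), capacity)
            templates = lexicons[crit].evidence_templates
            for _ in range(count):
                tpl = templates[int(rng.integers(len(templates)))]
                plan.append(("evidence", crit, _fill(tpl, rng, vocab)))
        for crit in _CRITERIA:
            conf = lexicons[crit].confounder_templates
            if conf and rng.random() < config.confounder_rate and len(plan) < n_sent:
                tpl = conf[int(rng.integers(len(conf)))]
                plan.append(("confounder", crit, _fill(tpl, rng, vocab)))
        while len(plan) < n_sent:
            tpl = _BACKGROUND_TEMPLATES[int(rng.integers(len(_BACKGROUND_TEMPLATES)))]
            plan.append(("background", None, _fill(tpl, rng, vocab)))

        order = rng.permutation(len(plan))
        placed = [plan[i] for i in order]
        gold: dict[Criterion, frozenset[int]] = {
            crit: frozenset(
                i for i, (kind, c, _) in enumerate(placed)
                if kind == "evidence" and c is crit
            )
            for crit in satisfied
        }
        body = " ".join(text for _, _, text in placed)
        article_id = f"syn-{config.seed}-{n:05d}"
        if len(split_sentences(body)) != len(placed):  # pragma: no cover
            raise AssertionError("template produced an unexpected sentence boundary")
        articles.append(
            NewsArticle(
                article_id=article_id,
                source_type="story" if rng.random() < 0.8 else "release",
                title=f"Health report {n}",
                body=body,
                ratings=ratings,
                gold_evidence=gold,
            )
        )
    return Corpus(articles)


def generate_sentence_dataset(
    corpus: Corpus, criterion: Criterion, seed: int
) -> SentenceDataset:
    """Build a balanced sentence-level dataset from gold evidence.

    Positives are all gold evidence sentences of articles rated satisfactory
    on the criterion; negatives are an equal number of sentences sampled
    uniformly without replacement from all remaining (non-gold) sentences,
    corpus-wide.
    """
    positives = []
    pool = []
    for article in corpus:
        sentences = article.sentences()
        gold = (article.gold_evidence or {}).get(criterion, frozenset())
        is_pos = article.ratings.get(criterion) is Rating.SATISFACTORY
        for s in sentences:
            if is_pos and s.index in gold:
                positives.append(s)
            else:
                pool.append(s)
    if not positives:
        return SentenceDataset(items=[], criterion=criterion, seed=seed)
    if len(pool) < len(positives):
        raise ValueError(
            f"only {len(pool)} non-gold sentences available for "
            f"{len(positives)} positives"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=len(positives), replace=False)
    negatives = [pool[int(i)] for i in chosen]
    items = [(s, 1) for s in positives] + [(s, 0) for s in negatives]
    return SentenceDataset(items=items, criterion=criterion, seed=seed)
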