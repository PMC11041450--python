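"""Text preprocessing and TF-IDF vectorization.

The normalization chain is: strip accents, lowercase, tokenize, drop tokens
containing digits, drop stop words, lemmatize (plural folding), then stem
(Porter). Everything is frozen in this module — no external word lists — so
the chain is byte-reproducible.

The TF-IDF model uses unigrams + bigrams, a vocabulary capped at
``max_features`` entries chosen by total corpus frequency (ties broken
lexicographically), smoothed idf ``ln((1+N)/(1+df)) + 1``, raw term counts,
and L2 normalization per document.
"""

from __future__ import annotations

import json
import math
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

# ---------------------------------------------------------------------------
# Stop words (frozen standard English list)
# ---------------------------------------------------------------------------

STOP_WORDS = frozenset("""
a about above after again against all almost also although am among an and
any are aren as at be because been before being below between both but by
can cannot could did do does doing down during each either few for from
further had has have having he her here hers herself him himself his how
however i if in into is it its itself just me might more most much must my
myself neither no nor not now of off on once only onto or other our ours
ourselves out over own per rather said same she should since so some such
than that the their theirs them themselves then there these they this those
through thus to too under until up upon very was we were what when where
whether which while who whom why will with within without would you your
yours yourself yourselves
""".split())

# ---------------------------------------------------------------------------
# Lemmatization: small irregular table + plural folding rules
# ---------------------------------------------------------------------------

_IRREGULAR = {
    "men": "man", "women": "woman", "children": "child", "feet": "foot",
    "teeth": "tooth", "mice": "mouse", "geese": "goose", "people": "person",
}


def lemmatize(token: str) -> str:
    """Fold plural nouns onto their singular form (verb inflection is left
    to the stemmer)."""
    if token in _IRREGULAR:
        return _IRREGULAR[token]
    if len(token) > 4 and token.endswith("ies"):
        return token[:-3] + "y"
    if len(token) > 3 and token.endswith(("ches", "shes", "sses", "xes", "zes")):
        return token[:-2]
    if len(token) > 3 and token.endswith("s") and not token.endswith(("ss", "us", "is")):
        return token[:-1]
    return token


# ---------------------------------------------------------------------------
# Porter stemmer
# ---------------------------------------------------------------------------

_VOWELS = "aeiou"


def _is_cons(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    n = 0
    i = 0
    length = len(stem)
    while i < length and _is_cons(stem, i):
        i += 1
    while i < length:
        while i < length and not _is_cons(stem, i):
            i += 1
        if i >= length:
            break
        n += 1
        while i < length and _is_cons(stem, i):
            i += 1
    return n


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return len(word) >= 2 and word[-1] == word[-2] and _is_cons(word, len(word) - 1)


def _cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    return (
        _is_cons(word, len(word) - 3)
        and not _is_cons(word, len(word) - 2)
        and _is_cons(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


_STEP2 = (
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
)

_STEP3 = (
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
)

_STEP4 = (
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
)


def porter_stem(word: str) -> str:
    """Classic Porter stemming; words of length <= 2 are returned unchanged."""
    if len(word) <= 2:
        return word
    w = word

    # step 1a
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif not w.endswith("ss") and w.endswith("s"):
        w = w[:-1]

    # step 1b
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    else:
        flag = False
        if w.endswith("ed") and _has_vowel(w[:-2]):
            w, flag = w[:-2], True
        elif w.endswith("ing") and _has_vowel(w[:-3]):
            w, flag = w[:-3], True
        if flag:
            if w.endswith(("at", "bl", "iz")):
                w += "e"
            elif _ends_double_cons(w) and w[-1] not in "lsz":
                w = w[:-1]
            elif _measure(w) == 1 and _cvc(w):
                w += "e"

    # step 1c
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"

    # step 2
    for suffix, repl in _STEP2:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 0:
                w = stem + repl
            break

    # step 3
    for suffix, repl in _STEP3:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 0:
                w = stem + repl
            break

    # step 4
    for suffix in _STEP4:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 1:
                if suffix == "ion" and not stem.endswith(("s", "t")):
                    break
                w = stem
            break

    # step 5a
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _cvc(stem)):
            w = stem

    # step 5b
    if _measure(w) > 1 and _ends_double_cons(w) and w.endswith("l"):
        w = w[:-1]

    return w


def normalize_token(token: str) -> str:
    """Lemmatize then stem, iterated to a fixed point.

    A single Porter pass is not idempotent on every output (e.g. a stem
    ending in a bare "s" loses it on a second pass); iterating until the
    form is stable makes the whole preprocessing chain idempotent."""
    current = token
    for _ in range(5):
        nxt = porter_stem(lemmatize(current))
        if nxt == current:
            return current
        current = nxt
    return current


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TokenDoc:
    """Normalized token sequence with per-token source-text offsets."""

    tokens: tuple[str, ...]
    origin_spans: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.tokens)


_WORD = re.compile(r"[a-z0-9']+")


def _strip_accents(text: str) -> tuple[str, list[int]]:
    """Decompose accented characters, dropping combining marks; returns the
    transformed string plus a map from transformed index to source index."""
    out: list[str] = []
    origin: list[int] = []
    for i, ch in enumerate(text):
        for c in unicodedata.normalize("NFKD", ch):
            if not unicodedata.combining(c):
                out.append(c)
                origin.append(i)
    return "".join(out), origin


def preprocess(text: str) -> TokenDoc:
    """Normalize raw text into a :class:`TokenDoc`.

    Applies accent stripping, lowercasing, tokenization, removal of tokens
    containing digits, stop-word removal, possessive stripping, then
    lemmatization and stemming. Deterministic; an empty or all-filtered text
    yields an empty TokenDoc.
    """
    flat, origin = _strip_accents(text)
    lowered = flat.lower()
    tokens: list[str] = []
    spans: list[tuple[int, int]] = []
    for m in _WORD.finditer(lowered):
        raw = m.group()
        if any(c.isdigit() for c in raw):
            continue
        raw = raw.strip("'")
        if raw.endswith("'s"):
            raw = raw[:-2]
        if len(raw) < 2 or raw in STOP_WORDS:
            continue
        norm = normalize_token(raw)
        if not norm:
            continue
        start = origin[m.start()]
        end = origin[m.end() - 1] + 1
        tokens.append(norm)
        spans.append((start, end))
    return TokenDoc(tokens=tuple(tokens), origin_spans=tuple(spans))


def ngrams_of(doc: TokenDoc | Sequence[str]) -> list[str]:
    """Unigrams and space-joined bigrams of a token sequence, in order."""
    toks = doc.tokens if isinstance(doc, TokenDoc) else tuple(doc)
    grams = list(toks)
    grams.extend(f"{a} {b}" for a, b in zip(toks, toks[1:]))
    return grams


# ---------------------------------------------------------------------------
# TF-IDF
# ---------------------------------------------------------------------------

@dataclass
class TfidfModel:
    """Fitted TF-IDF vocabulary and idf weights over unigrams + bigrams."""

    vocabulary: dict[str, int]
    idf: np.ndarray
    max_features: int
    n_docs: int
    _inverse: dict[int, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._inverse:
            self._inverse = {i: g for g, i in self.vocabulary.items()}

    def ngram_for(self, column: int) -> str:
        return self._inverse[column]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "max_features": self.max_features,
            "n_docs": self.n_docs,
            "vocabulary": self.vocabulary,
            "idf": self.idf.tolist(),
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "TfidfModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            vocabulary=payload["vocabulary"],
            idf=np.asarray(payload["idf"], dtype=float),
            max_features=payload["max_features"],
            n_docs=payload["n_docs"],
        )


def fit_tfidf(docs: Sequence[TokenDoc], max_features: int) -> TfidfModel:
    """Fit the vocabulary and idf weights.

    The vocabulary is the ``max_features`` most frequent n-grams by total
    corpus count, ties broken lexicographically; column indices follow
    lexicographic order. idf(t) = ln((1+N)/(1+df(t))) + 1.
    """
    if len(docs) == 0:
        raise ValueError("cannot fit TF-IDF on an empty corpus")
    if len(docs) < 2:
        raise ValueError("TF-IDF requires at least 2 documents")
    total: Counter[str] = Counter()
    df: Counter[str] = Counter()
    for doc in docs:
        grams = ngrams_of(doc)
        total.update(grams)
        df.update(set(grams))
    selected = sorted(total, key=lambda g: (-total[g], g))[:max_features]
    selected.sort()
    vocabulary = {g: i for i, g in enumerate(selected)}
    n = len(docs)
    idf = np.array(
        [math.log((1 + n) / (1 + df[g])) + 1.0 for g in selected], dtype=float
    )
    return TfidfModel(vocabulary=vocabulary, idf=idf, max_features=max_features, n_docs=n)


def vectorize(model: TfidfModel, doc: TokenDoc | Sequence[str]) -> sp.csr_matrix:
    """Raw-count tf x idf, L2-normalized; out-of-vocabulary n-grams ignored.

    Returns a 1 x |V| sparse row; an all-OOV document yields a zero vector.
    """
    counts = Counter(g for g in ngrams_of(doc) if g in model.vocabulary)
    if not counts:
        return sp.csr_matrix((1, len(model.vocabulary)))
    cols = np.array(sorted(model.vocabulary[g] for g in counts), dtype=np.int32)
    tf = np.array([counts[model.ngram_for(int(c))] for c in cols], dtype=float)
    weights = tf * model.idf[cols]
    norm = float(np.linalg.norm(weights))
    if norm > 0:
        weights = weights / norm
    return sp.csr_matrix(
        (weights, (np.zeros_like(cols), cols)), shape=(1, len(model.vocabulary))
    )


def transform(model: TfidfModel, docs: Iterable[TokenDoc | Sequence[str]]) -> sp.csr_matrix:
    """Vectorize a collection into a stacked sparse matrix."""
    rows = [vectorize(model, d) for d in docs]
    if not rows:
        return sp.csr_matrix((0, len(model.vocabulary)))
    return sp.vstack(rows, format="csr")
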