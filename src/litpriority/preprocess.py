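"""Abstracts -> pruned lemma vocabulary -> TF-IDF document-term matrix.

Tokenization lowercases and strips punctuation/digits; a rule-plus-lexicon
lemmatizer maps tokens to lemmas; stop words (including scientific
boilerplate like "introduction"/"method") are removed after lemmatization.
Lemmas with absolute frequency below 4 or document frequency above 80% of
the corpus are pruned, and the retained lemmas are weighted as
tf(i,j) * ln(n / df(j)) — raw term counts, unsmoothed idf, no row
normalization (ubiquitous terms are already pruned by the 80% rule).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmwrite

__all__ = [
    "Vocabulary",
    "TermMatrix",
    "default_stop_list",
    "lemmatize",
    "tokenize_and_lemmatize",
    "build_vocabulary",
    "build_tfidf",
    "save_term_matrix",
]

_TOKEN = re.compile(r"[a-z]+")


def _load_resource_lines(name: str) -> list[str]:
    text = resources.files("litpriority.resources").joinpath(name).read_text("utf-8")
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def default_stop_list() -> frozenset[str]:
    """Stop lemmas shipped with the package (function words + boilerplate)."""
    return frozenset(_load_resource_lines("stoplist.txt"))


def _load_exceptions() -> dict[str, str]:
    pairs = (ln.split() for ln in _load_resource_lines("lemma_exceptions.txt"))
    return {surface: lemma for surface, lemma in pairs}


_EXCEPTIONS: dict[str, str] | None = None


def lemmatize(token: str) -> str:
    """Map a lowercase token to its lemma.

    Lexicon of irregular forms first, then English inflection rules
    (plural stripping, -ies/-es/-s).  Unknown words pass through
    unchanged, so synthetic lemma tokens ("w0001", ...) are stable.
    """
    global _EXCEPTIONS
    if _EXCEPTIONS is None:
        _EXCEPTIONS = _load_exceptions()
    hit = _EXCEPTIONS.get(token)
    if hit is not None:
        return hit
    n = len(token)
    if n > 4 and token.endswith("ies"):
        return token[:-3] + "y"
    if n > 4 and token.endswith(("sses", "shes", "ches", "xes", "zes", "oes")):
        return token[:-2]
    if n > 3 and token.endswith("s") and not token.endswith(("ss", "us", "is")):
        return token[:-1]
    return token


def tokenize_and_lemmatize(
    abstract: str, stop_list: Iterable[str] | None = None
) -> list[str]:
    """Lowercase, strip punctuation/numbers, lemmatize, drop stop lemmas.

    The stop list is applied to *lemmas* (so "method" also removes
    "methods").  Single-letter tokens are discarded.  An abstract that
    reduces to nothing yields an empty list; such documents are dropped
    later when the term matrix is built.
    """
    stops = frozenset(stop_list) if stop_list is not None else default_stop_list()
    out: list[str] = []
    for tok in _TOKEN.findall(abstract.lower()):
        lemma = lemmatize(tok)
        if len(lemma) > 1 and lemma not in stops:
            out.append(lemma)
    return out


@dataclass(frozen=True)
class Vocabulary:
    """Retained lemma inventory with corpus frequencies.

    ``lemmas`` is lexicographically ordered; ``abs_freq[j]`` is the total
    occurrence count of lemma j, ``doc_freq[j]`` the number of documents
    containing it.
    """

    lemmas: tuple[str, ...]
    abs_freq: np.ndarray
    doc_freq: np.ndarray
    n_docs: int

    def __len__(self) -> int:
        return len(self.lemmas)

    @property
    def index(self) -> dict[str, int]:
        return {lemma: j for j, lemma in enumerate(self.lemmas)}


@dataclass
class TermMatrix:
    """TF-IDF representation R: an n x m sparse non-negative matrix."""

    values: sp.csr_matrix
    row_ids: tuple[str, ...]
    vocabulary: Vocabulary
    dropped_rows: tuple[str, ...] = ()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def build_vocabulary(
    token_docs: Sequence[Sequence[str]],
    min_abs_freq: int = 4,
    max_rel_df: float = 0.8,
) -> Vocabulary:
    """Prune the lemma inventory by absolute and relative frequency.

    A lemma is retained iff its total occurrence count is at least
    ``min_abs_freq`` and it appears in at most ``max_rel_df`` of the
    documents.  Order is lexicographic for determinism.
    """
    n = len(token_docs)
    if n == 0 or all(not d for d in token_docs):
        raise ValueError("need at least one non-empty tokenized document")
    totals: Counter[str] = Counter()
    docfreq: Counter[str] = Counter()
    for doc in token_docs:
        totals.update(doc)
        docfreq.update(set(doc))
    kept = sorted(
        lemma
        for lemma, cnt in totals.items()
        if cnt >= min_abs_freq and docfreq[lemma] <= max_rel_df * n
    )
    if not kept:
        raise ValueError(
            "vocabulary empty after pruning; lower min_abs_freq or raise max_rel_df"
        )
    return Vocabulary(
        lemmas=tuple(kept),
        abs_freq=np.array([totals[w] for w in kept], dtype=np.int64),
        doc_freq=np.array([docfreq[w] for w in kept], dtype=np.int64),
        n_docs=n,
    )


def build_tfidf(
    token_docs: Sequence[Sequence[str]],
    vocab: Vocabulary,
    doc_ids: Sequence[str] | None = None,
) -> TermMatrix:
    """Weight retained lemmas as raw tf times ln(n/df).

    ``n`` is the number of documents the vocabulary was built from.
    Documents whose row comes out all zero (nothing retained) are dropped
    and listed in ``dropped_rows``.
    """
    if doc_ids is None:
        doc_ids = [f"doc{i}" for i in range(len(token_docs))]
    if len(doc_ids) != len(token_docs):
        raise ValueError("doc_ids and token_docs length mismatch")
    index = vocab.index
    idf = np.log(vocab.n_docs / vocab.doc_freq.astype(float))
    rows, cols, vals = [], [], []
    for i, doc in enumerate(token_docs):
        counts = Counter(lemma for lemma in doc if lemma in index)
        for lemma, tf in counts.items():
            j = index[lemma]
            rows.append(i)
            cols.append(j)
            vals.append(tf * idf[j])
    mat = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(token_docs), len(vocab)), dtype=np.float64
    )
    row_mass = np.asarray(mat.sum(axis=1)).ravel()
    keep = row_mass > 0
    dropped = tuple(d for d, k in zip(doc_ids, keep) if not k)
    kept_ids = tuple(d for d, k in zip(doc_ids, keep) if k)
    return TermMatrix(
        values=mat[keep], row_ids=kept_ids, vocabulary=vocab, dropped_rows=dropped
    )


def save_term_matrix(tm: TermMatrix, stem: str | Path) -> None:
    """Write ``<stem>.mtx`` (Matrix Market) plus ``<stem>.lemmas.txt`` sidecar."""
    stem = Path(stem)
    mmwrite(str(stem.with_suffix(".mtx")), tm.values)
    stem.with_suffix(".lemmas.txt").write_text("\n".join(tm.vocabulary.lemmas) + "\n")
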