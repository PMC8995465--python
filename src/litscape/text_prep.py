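"""Bag-of-words preprocessing of abstracts.

Topic modeling operates on word counts over a fixed vocabulary.  The pipeline
here is deliberately simple and fully deterministic: lower-case alphabetic
tokenization, stopword removal, a document-frequency floor, no stemming.
"""

from __future__ import annotations

import csv
import importlib.resources
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Vocabulary",
    "BowCorpus",
    "tokenize",
    "load_stopwords",
    "build_vocabulary",
    "to_bow",
    "build_corpus",
]

_TOKEN_RE = re.compile(r"[a-z]+")


def tokenize(text: str) -> list[str]:
    """Lower-cased alphabetic tokens; punctuation and numbers are dropped.

    Hyphenated compounds split into their parts ("gemcitabine-based" ->
    ["gemcitabine", "based"]); standalone numbers vanish.  Idempotent when
    re-applied to its own space-joined output.
    """
    return _TOKEN_RE.findall(text.lower())


def load_stopwords() -> frozenset[str]:
    """The packaged English stopword list."""
    path = importlib.resources.files("litscape.data") / "stopwords.txt"
    with path.open() as fh:
        return frozenset(w.strip() for w in fh if w.strip())


@dataclass
class Vocabulary:
    """Ordered term list with a document-frequency floor.

    ``terms`` is lexicographically sorted so construction is independent of
    document order; ``index`` maps each term to its position; ``doc_freq``
    records in how many fitting documents each term occurred.
    """

    terms: list[str]
    min_df: int
    stopwords: frozenset[str]
    doc_freq: dict[str, int] = field(default_factory=dict)
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["term", "doc_freq"])
            for t in self.terms:
                writer.writerow([t, self.doc_freq.get(t, 0)])


@dataclass
class BowCorpus:
    """Sparse bag-of-words corpus aligned with document identifiers."""

    docs: list[dict[int, int]]
    doc_ids: list[str]
    vocab: Vocabulary

    def __post_init__(self) -> None:
        if len(self.docs) != len(self.doc_ids):
            raise ValueError("docs and doc_ids must be aligned")

    @property
    def n_tokens(self) -> int:
        return sum(c for doc in self.docs for c in doc.values())

    def __len__(self) -> int:
        return len(self.docs)


def build_vocabulary(
    token_lists: Sequence[Sequence[str]],
    min_df: int = 5,
    stopwords: Optional[frozenset[str]] = None,
) -> Vocabulary:
    """Build a vocabulary from tokenized documents.

    Document frequency counts distinct-per-document occurrences; terms below
    ``min_df`` documents or in ``stopwords`` are excluded.  The result is the
    same for any permutation of the input documents.
    """
    if min_df < 1:
        raise ValueError("min_df must be >= 1")
    if stopwords is None:
        stopwords = load_stopwords()
    df: dict[str, int] = {}
    for tokens in token_lists:
        for term in set(tokens):
            if term not in stopwords:
                df[term] = df.get(term, 0) + 1
    terms = sorted(t for t, n in df.items() if n >= min_df)
    if not terms:
        logger.warning("empty vocabulary (corpus too small for min_df=%d)", min_df)
    return Vocabulary(
        terms=terms,
        min_df=min_df,
        stopwords=stopwords,
        doc_freq={t: df[t] for t in terms},
    )


def to_bow(tokens: Iterable[str], vocab: Vocabulary) -> dict[int, int]:
    """Count in-vocabulary tokens; out-of-vocabulary tokens are dropped."""
    counts: dict[int, int] = {}
    for tok in tokens:
        idx = vocab.index.get(tok)
        if idx is not None:
            counts[idx] = counts.get(idx, 0) + 1
    return counts


def build_corpus(
    records,
    min_df: int = 5,
    stopwords: Optional[frozenset[str]] = None,
    use_title: bool = False,
) -> BowCorpus:
    """Tokenize record abstracts (optionally with titles) into a BowCorpus."""
    texts = [
        (r.title + " " + r.abstract) if use_title else r.abstract for r in records
    ]
    token_lists = [tokenize(t) for t in texts]
    vocab = build_vocabulary(token_lists, min_df=min_df, stopwords=stopwords)
    docs = [to_bow(tokens, vocab) for tokens in token_lists]
    return BowCorpus(docs=docs, doc_ids=[r.pmid for r in records], vocab=vocab)
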