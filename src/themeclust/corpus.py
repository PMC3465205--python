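"""Corpus ingestion and the binary term-document incidence relation.

Documents are read from plain-text directories, JSON Lines, or tab-separated
(id, title, abstract) records, tokenized, stopword-filtered, and turned into
a binary term-by-document incidence matrix over unigram and adjacent-token
bigram terms.  The incidence relation is the sole input to the clustering
model: entry (t, d) records whether term t occurs in document d at all —
occurrence counts are deliberately discarded because the downstream model is
a Bernoulli occurrence model.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "DEFAULT_STOPWORDS",
    "Document",
    "TermVocabulary",
    "IncidenceRelation",
    "EmptyVocabularyError",
    "tokenize",
    "extract_terms",
    "build_incidence",
    "read_text_dir",
    "read_jsonl",
    "read_tsv",
    "load_stopwords",
    "write_incidence",
    "read_incidence",
]

# A conventional English stopword list (function words and high-frequency
# verbs).  Callers may supply their own set; this default is deliberately
# small and fully visible rather than borrowed from any external resource.
DEFAULT_STOPWORDS: frozenset[str] = frozenset("""
a about above after again against all am an and any are as at be because
been before being below between both but by can did do does doing down
during each few for from further had has have having he her here hers
herself him himself his how i if in into is it its itself just me more
most my myself no nor not now of off on once only or other our ours
ourselves out over own same she should so some such than that the their
theirs them themselves then there these they this those through to too
under until up very was we were what when where which while who whom why
will with you your yours yourself yourselves
""".split())

_TOKEN_RE = re.compile(r"\w+")


class EmptyVocabularyError(ValueError):
    """No term survived preprocessing and the document-frequency floor."""


@dataclass
class Document:
    """One text document: raw text plus its normalized token stream."""

    doc_id: str
    text: str
    tokens: list[str] = field(default_factory=list)


def tokenize(text: str, stopwords: Iterable[str] | None = None) -> list[str]:
    """Lowercase, split into word tokens, and drop stopwords.

    Tokens are maximal runs of word characters (letters, digits,
    underscore); punctuation is stripped.  Order is preserved.  An empty
    text yields an empty list.
    """
    stop = DEFAULT_STOPWORDS if stopwords is None else frozenset(stopwords)
    return [tok for tok in _TOKEN_RE.findall(text.lower()) if tok not in stop]


def extract_terms(tokens: Sequence[str], use_bigrams: bool = True) -> set[str]:
    """Distinct unigrams plus (optionally) adjacent-token bigrams.

    Bigrams are formed over the already stopword-filtered stream and
    rendered as the two tokens joined by a single space, so "deep brain
    stimulation" yields the terms {deep, brain, stimulation, "deep brain",
    "brain stimulation"}.
    """
    terms = set(tokens)
    if use_bigrams:
        terms.update(f"{a} {b}" for a, b in zip(tokens, tokens[1:]))
    return terms


@dataclass
class TermVocabulary:
    """Ordered term list with a term -> column index bijection."""

    terms: list[str]
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.terms)}
        if len(self.index) != len(self.terms):
            raise ValueError("duplicate terms in vocabulary")

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class IncidenceRelation:
    """Binary term-by-document incidence: entry (t, d) = 1 iff t occurs in d.

    ``incidence`` is a CSR matrix of shape (n_terms, n_docs) with {0,1}
    entries.  ``term_doc_freq`` caches the per-term document frequency n_t
    and ``n_docs`` the corpus size N.
    """

    vocabulary: TermVocabulary
    doc_ids: list[str]
    incidence: sp.csr_matrix

    def __post_init__(self) -> None:
        self.incidence = sp.csr_matrix(self.incidence, dtype=np.int8)
        self.incidence.eliminate_zeros()
        if self.incidence.shape != (len(self.vocabulary), len(self.doc_ids)):
            raise ValueError("incidence shape does not match vocabulary/doc ids")
        if self.incidence.nnz and not np.all(self.incidence.data == 1):
            raise ValueError("incidence entries must be binary")
        self.term_doc_freq = np.asarray(
            self.incidence.sum(axis=1), dtype=np.int64
        ).ravel()

    @property
    def n_docs(self) -> int:
        return len(self.doc_ids)

    @property
    def n_terms(self) -> int:
        return len(self.vocabulary)


def build_incidence(
    documents: Sequence[Document],
    min_doc_freq: int = 2,
    use_bigrams: bool = True,
) -> IncidenceRelation:
    """Build the binary incidence relation over all extracted terms.

    Terms occurring in fewer than ``min_doc_freq`` documents are dropped.
    Term order is lexicographic and document order is input order, so the
    matrix is fully reproducible.  Raises :class:`EmptyVocabularyError` when
    no term survives.
    """
    if not documents:
        raise ValueError("no documents supplied")
    if min_doc_freq < 1:
        raise ValueError("min_doc_freq must be >= 1")
    doc_ids = [d.doc_id for d in documents]
    if len(set(doc_ids)) != len(doc_ids):
        raise ValueError("duplicate doc_id values in corpus")

    doc_terms = [extract_terms(d.tokens, use_bigrams) for d in documents]
    df: dict[str, int] = {}
    for terms in doc_terms:
        for t in terms:
            df[t] = df.get(t, 0) + 1
    kept = sorted(t for t, n in df.items() if n >= min_doc_freq)
    if not kept:
        raise EmptyVocabularyError(
            f"empty vocabulary: no term occurs in >= {min_doc_freq} documents"
        )
    vocab = TermVocabulary(kept)

    rows, cols = [], []
    for j, terms in enumerate(doc_terms):
        for t in terms:
            i = vocab.index.get(t)
            if i is not None:
                rows.append(i)
                cols.append(j)
    mat = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(vocab), len(documents)),
    )
    return IncidenceRelation(vocab, doc_ids, mat)


# ---------------------------------------------------------------------------
# Readers


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Stopword file: one word per line; blank lines ignored."""
    words = Path(path).read_text(encoding="utf-8").split()
    return frozenset(w.lower() for w in words)


def _make_documents(
    records: Iterable[tuple[str, str]], stopwords: Iterable[str] | None
) -> list[Document]:
    return [Document(i, text, tokenize(text, stopwords)) for i, text in records]


def read_text_dir(
    path: str | Path, stopwords: Iterable[str] | None = None
) -> list[Document]:
    """One document per file; doc_id is the filename. Files sorted by name."""
    root = Path(path)
    files = sorted(p for p in root.iterdir() if p.is_file())
    return _make_documents(
        ((p.name, p.read_text(encoding="utf-8")) for p in files), stopwords
    )


def read_jsonl(
    path: str | Path, stopwords: Iterable[str] | None = None
) -> list[Document]:
    """JSON Lines with one object per line carrying "id" and "text"."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            records.append((str(obj["id"]), str(obj["text"])))
    return _make_documents(records, stopwords)


def read_tsv(
    path: str | Path, stopwords: Iterable[str] | None = None
) -> list[Document]:
    """Tab-separated id / title / abstract; title and abstract concatenated."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"expected 3 tab-separated columns, got: {line!r}")
            doc_id, title, abstract = parts[0], parts[1], parts[2]
            records.append((doc_id, f"{title} {abstract}"))
    return _make_documents(records, stopwords)


# ---------------------------------------------------------------------------
# Sparse export


def write_incidence(relation: IncidenceRelation, prefix: str | Path) -> None:
    """Write PREFIX.mtx (Matrix Market, 1-based) plus PREFIX.terms.txt and
    PREFIX.docs.txt sidecars, one entry per line."""
    prefix = Path(prefix)
    mmwrite(str(prefix) + ".mtx", relation.incidence.tocoo(), field="integer")
    prefix.with_suffix(prefix.suffix + ".terms.txt").write_text(
        "\n".join(relation.vocabulary.terms) + "\n", encoding="utf-8"
    )
    prefix.with_suffix(prefix.suffix + ".docs.txt").write_text(
        "\n".join(relation.doc_ids) + "\n", encoding="utf-8"
    )


def read_incidence(prefix: str | Path) -> IncidenceRelation:
    """Inverse of :func:`write_incidence`; reproduces the incidence exactly."""
    prefix = Path(prefix)
    mat = sp.csr_matrix(mmread(str(prefix) + ".mtx"), dtype=np.int8)
    terms = prefix.with_suffix(prefix.suffix + ".terms.txt").read_text(
        encoding="utf-8"
    ).splitlines()
    docs = prefix.with_suffix(prefix.suffix + ".docs.txt").read_text(
        encoding="utf-8"
    ).splitlines()
    return IncidenceRelation(TermVocabulary(terms), docs, mat)
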