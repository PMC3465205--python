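"""Clustering-quality, stability and enrichment metrics.

Normalized mutual information (NMI) scores a predicted partition against a
gold standard; the paired F-score compares the subject-term output of two
runs through their within-cluster term pairs; title scoring picks one short
phrase summarizing a cluster; hypergeometric enrichment flags document
labels (e.g. controlled-vocabulary annotations) over-represented in a
cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .corpus import Document
from .em import ClusterThemeModel

__all__ = [
    "ContingencyTable",
    "TitleCandidate",
    "EnrichmentResult",
    "nmi",
    "paired_fscore",
    "title_score",
    "select_title",
    "select_title_from_terms",
    "label_enrichment",
]


@dataclass
class ContingencyTable:
    """Joint document counts between a predicted and an answer partition.

    ``joint[h, l]`` is m_{h,l}, the number of documents in predicted
    cluster h and answer cluster l; row and column sums give the cluster
    sizes m_h and c_l, both summing to the corpus size m.
    """

    joint: np.ndarray

    def __post_init__(self) -> None:
        self.joint = np.asarray(self.joint, dtype=np.int64)
        self.row_sizes = self.joint.sum(axis=1)
        self.col_sizes = self.joint.sum(axis=0)
        self.m = int(self.joint.sum())

    @classmethod
    def from_assignments(
        cls, predicted: Sequence, truth: Sequence
    ) -> "ContingencyTable":
        if len(predicted) != len(truth):
            raise ValueError("assignments cover different document sets")
        if len(predicted) == 0:
            raise ValueError("empty assignments")
        _, pi = np.unique(np.asarray(predicted), return_inverse=True)
        _, ti = np.unique(np.asarray(truth), return_inverse=True)
        joint = np.zeros((pi.max() + 1, ti.max() + 1), dtype=np.int64)
        np.add.at(joint, (pi, ti), 1)
        return cls(joint)


def nmi(predicted: Sequence, truth: Sequence) -> float:
    """Normalized mutual information between two partitions, in [0, 1].

    NMI = sum_{h,l} m_{h,l} log(m m_{h,l} / (m_h c_l))
          / sqrt( sum_h m_h log(m_h/m) * sum_l c_l log(c_l/m) )

    with natural logs (the base cancels) and 0 log 0 = 0.  A perfect match
    scores 1; statistically independent partitions score 0.  When either
    side is a single cluster both entropies vanish and the ratio is 0/0;
    the convention used is 1 for identical partitions and 0 otherwise.
    """
    table = ContingencyTable.from_assignments(predicted, truth)
    m = table.m
    mh = table.row_sizes.astype(float)
    cl = table.col_sizes.astype(float)
    if len(mh) == 1 or len(cl) == 1:
        return 1.0 if len(mh) == 1 and len(cl) == 1 else 0.0
    joint = table.joint.astype(float)
    nz = joint > 0
    num = float(
        np.sum(joint[nz] * np.log(m * joint[nz] / np.outer(mh, cl)[nz]))
    )
    denom = float(
        np.sqrt(np.sum(mh * np.log(mh / m)) * np.sum(cl * np.log(cl / m)))
    )
    return num / denom


def _pair_set(term_sets: Iterable[Iterable[str]]) -> set[frozenset[str]]:
    pairs: set[frozenset[str]] = set()
    for terms in term_sets:
        for a, b in combinations(sorted(set(terms)), 2):
            pairs.add(frozenset((a, b)))
    return pairs


def paired_fscore(
    terms_a: Iterable[Iterable[str]], terms_b: Iterable[Iterable[str]]
) -> float:
    """Paired F-score between the subject-term sets of two runs.

    Each side contributes the union over its clusters of unordered
    within-cluster term pairs; precision and recall are the shared-pair
    fractions of each side and F is their harmonic mean (0 when no pair is
    shared).  Symmetric in its arguments.
    """
    pairs_a = _pair_set(terms_a)
    pairs_b = _pair_set(terms_b)
    if not pairs_a or not pairs_b:
        raise ValueError("a side generates no term pairs")
    common = len(pairs_a & pairs_b)
    if common == 0:
        return 0.0
    precision = common / len(pairs_a)
    recall = common / len(pairs_b)
    return 2.0 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# Cluster titles


@dataclass
class TitleCandidate:
    """A candidate cluster title with its score T(P) and supporting terms."""

    phrase: tuple[str, ...]
    score: float
    supporting_terms: list[tuple[str, float, int]]

    @property
    def text(self) -> str:
        return " ".join(self.phrase)


def _phrase_contains(phrase: Sequence[str], term: str) -> bool:
    """Unigram: token membership; bigram: consecutive-token containment."""
    parts = term.split(" ")
    if len(parts) == 1:
        return term in phrase
    return any(
        tuple(phrase[i : i + len(parts)]) == tuple(parts)
        for i in range(len(phrase) - len(parts) + 1)
    )


def title_score(
    phrase: Sequence[str],
    alpha: Mapping[str, float],
    doc_freq: Mapping[str, int],
) -> float:
    """T(P) = sum over subject terms t contained in P of alpha_t * DF(t)."""
    if not phrase:
        raise ValueError("empty phrase")
    return float(
        sum(
            a * doc_freq.get(t, 0)
            for t, a in alpha.items()
            if _phrase_contains(phrase, t)
        )
    )


def select_title(
    cluster_docs: Sequence[Document],
    model: ClusterThemeModel,
    terms: Sequence[str],
    max_len: int = 4,
) -> TitleCandidate:
    """Pick the highest-T(P) phrase occurring in a cluster's documents.

    Candidate phrases are all contiguous token windows of length 1..max_len
    from the cluster's documents.  DF(t) is the document frequency of the
    subject term within the cluster.  Ties break to the shorter phrase,
    then lexicographically.
    """
    subject = {terms[i]: float(model.alpha[i]) for i in model.subject_terms}
    return select_title_from_terms(cluster_docs, subject, max_len)


def select_title_from_terms(
    cluster_docs: Sequence[Document],
    subject: Mapping[str, float],
    max_len: int = 4,
) -> TitleCandidate:
    """As :func:`select_title`, from a subject-term -> alpha mapping."""
    if not cluster_docs:
        raise ValueError("empty cluster")
    df: dict[str, int] = {}
    for doc in cluster_docs:
        present = {t for t in subject if _phrase_contains(doc.tokens, t)}
        for t in present:
            df[t] = df.get(t, 0) + 1

    candidates: set[tuple[str, ...]] = set()
    for doc in cluster_docs:
        toks = doc.tokens
        for n in range(1, max_len + 1):
            for i in range(len(toks) - n + 1):
                candidates.add(tuple(toks[i : i + n]))
    if not candidates:
        raise ValueError("no candidate phrases (all documents empty)")

    best: TitleCandidate | None = None
    for phrase in sorted(candidates, key=lambda p: (len(p), p)):
        score = title_score(phrase, subject, df)
        if best is None or score > best.score:
            support = [
                (t, subject[t], df.get(t, 0))
                for t in sorted(subject)
                if _phrase_contains(phrase, t)
            ]
            best = TitleCandidate(phrase, score, support)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Label enrichment


@dataclass
class EnrichmentResult:
    """Hypergeometric over-representation of one label in one cluster."""

    label: str
    p_value: float
    cluster_size: int
    label_in_cluster: int
    label_in_corpus: int
    corpus_size: int


def label_enrichment(
    cluster_doc_ids: Iterable[str],
    doc_labels: Mapping[str, Iterable[str]],
    corpus_doc_ids: Iterable[str],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric p-values for labels present in a cluster.

    For a label occurring in K of the M corpus documents and k of the
    cluster's n documents, the p-value is P(X >= k) with X hypergeometric
    (M, K, n).  Results sorted ascending by p-value, then by label.
    """
    corpus = list(corpus_doc_ids)
    cluster = set(cluster_doc_ids)
    if not cluster <= set(corpus):
        raise ValueError("cluster is not a subset of the corpus")
    m_total = len(corpus)
    n_cluster = len(cluster)
    corpus_counts: dict[str, int] = {}
    cluster_counts: dict[str, int] = {}
    for d in corpus:
        for lab in set(doc_labels.get(d, ())):
            corpus_counts[lab] = corpus_counts.get(lab, 0) + 1
            if d in cluster:
                cluster_counts[lab] = cluster_counts.get(lab, 0) + 1
    results = [
        EnrichmentResult(
            label=lab,
            p_value=float(
                hypergeom.sf(k - 1, m_total, corpus_counts[lab], n_cluster)
            ),
            cluster_size=n_cluster,
            label_in_cluster=k,
            label_in_corpus=corpus_counts[lab],
            corpus_size=m_total,
        )
        for lab, k in cluster_counts.items()
    ]
    results.sort(key=lambda r: (r.p_value, r.label))
    return results
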