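"""Planted-theme synthetic corpora with known labels and theme vocabularies.

Each document belongs to exactly one latent theme.  Its term set is drawn
by independent Bernoulli trials: terms of its own theme occur with
probability ``p_in``, terms of other themes with ``p_out`` and background
terms with ``p_background`` — the same independent-occurrence assumption
the clustering model makes, so planted corpora are the natural ground truth
for parameter- and label-recovery tests.  Presence-only generation (no term
counts, no document-length or Zipf modelling) matches the model's Bernoulli
semantics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Document

__all__ = ["PlantedCorpusSpec", "PlantedCorpus", "generate", "expected_term_stats"]


@dataclass(frozen=True)
class PlantedCorpusSpec:
    """Generative description of a planted-theme corpus.

    ``two_token_themes`` renders each theme term as two adjacent tokens so
    that bigram extraction is exercised; by default terms are single tokens
    like ``theme2_term7`` that pass through tokenization unchanged.
    """

    n_themes: int = 3
    docs_per_theme: int = 100
    theme_vocab_size: int = 30
    background_vocab_size: int = 500
    p_in: float = 0.3
    p_out: float = 0.01
    p_background: float = 0.05
    seed: int = 0
    two_token_themes: bool = False

    def __post_init__(self) -> None:
        if min(self.n_themes, self.docs_per_theme, self.theme_vocab_size,
               self.background_vocab_size) < 1:
            raise ValueError("all counts must be >= 1")
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if not 0.0 <= self.p_background <= 1.0:
            raise ValueError("p_background must lie in [0, 1]")

    @property
    def n_docs(self) -> int:
        return self.n_themes * self.docs_per_theme


@dataclass
class PlantedCorpus:
    """Generated documents plus the planted labels and theme vocabularies."""

    documents: list[Document]
    labels: np.ndarray
    theme_terms: list[list[str]]


def _theme_term(spec: PlantedCorpusSpec, theme: int, j: int) -> str:
    if spec.two_token_themes:
        return f"theme{theme}x{j}a theme{theme}x{j}b"
    return f"theme{theme}_term{j}"


def generate(spec: PlantedCorpusSpec) -> PlantedCorpus:
    """Draw a corpus from the spec; byte-identical for a fixed seed.

    Each document's text lists its present terms in a per-document shuffled
    order (two-token theme terms stay adjacent, forming their bigram).
    """
    rng = np.random.default_rng(spec.seed)
    theme_terms = [
        [_theme_term(spec, i, j) for j in range(spec.theme_vocab_size)]
        for i in range(spec.n_themes)
    ]
    bg_terms = [f"bg_term{j}" for j in range(spec.background_vocab_size)]

    documents: list[Document] = []
    labels = np.repeat(np.arange(spec.n_themes), spec.docs_per_theme)
    for idx, lab in enumerate(labels):
        present: list[str] = []
        for i in range(spec.n_themes):
            prob = spec.p_in if i == lab else spec.p_out
            draws = rng.random(spec.theme_vocab_size) < prob
            present.extend(t for t, hit in zip(theme_terms[i], draws) if hit)
        draws = rng.random(spec.background_vocab_size) < spec.p_background
        present.extend(t for t, hit in zip(bg_terms, draws) if hit)
        rng.shuffle(present)
        text = " ".join(present)
        documents.append(Document(f"d{idx:05d}", text, text.split()))
    return PlantedCorpus(documents, labels, theme_terms)


def expected_term_stats(spec: PlantedCorpusSpec) -> dict[str, dict[str, float]]:
    """Closed-form expectations for each planted term class.

    Under the true labels a theme term has within-theme occurrence
    probability p_in, outside-theme probability p_out and marginal rate
    r = (docs_per_theme*p_in + (n_themes-1)*docs_per_theme*p_out) / N;
    background terms have all three equal to p_background.
    """
    n = spec.n_docs
    r_theme = (
        spec.docs_per_theme * spec.p_in
        + (spec.n_themes - 1) * spec.docs_per_theme * spec.p_out
    ) / n
    return {
        "theme": {
            "p_in": spec.p_in,
            "p_out": spec.p_out,
            "r": r_theme,
            "n_t": r_theme * n,
        },
        "background": {
            "p_in": spec.p_background,
            "p_out": spec.p_background,
            "r": spec.p_background,
            "n_t": spec.p_background * n,
        },
    }
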