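import numpy as np
import pytest

from themeclust import build_incidence
from themeclust.synthetic import PlantedCorpusSpec, generate


@pytest.fixture(scope="session")
def planted():
    """The reference planted corpus: 3 themes x 100 docs, 30 theme terms per
    theme, 500 background terms, p_in=0.3, p_out=0.01, p_bg=0.05."""
    spec = PlantedCorpusSpec(seed=0)
    return spec, generate(spec)


@pytest.fixture(scope="session")
def planted_relation(planted):
    _, corpus = planted
    return build_incidence(corpus.documents, min_doc_freq=2, use_bigrams=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
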