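import pytest

from gatascan.pipeline import RunConfig, annotate
from gatascan.synthetic_data import SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def corpus():
    """Default study-condition corpus (5 classes x 10 genes, no mutation)."""
    return generate_corpus(SynthConfig(seed=17))


@pytest.fixture(scope="session")
def annotated(corpus):
    return annotate(corpus.genome, corpus.models, cfg=RunConfig(species="synthetica"))


@pytest.fixture(scope="session")
def small_corpus():
    """A reduced corpus for fast bundle/IO tests."""
    cfg = SynthConfig(seed=3,
                      class_counts={"ELT1": 2, "ELT2": 2, "ELT3": 2, "ELT5": 2, "ELTX": 1},
                      paralog_plan=(("ELT3", 2600, "convergent"),))
    return generate_corpus(cfg)
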