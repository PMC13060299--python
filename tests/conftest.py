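import numpy as np
import pytest

from cytoset.core import CytometrySample, MarkerVocabulary
from cytoset.model import CytoTransformer, ModelConfig


@pytest.fixture
def vocab():
    return MarkerVocabulary(["CD3", "CD4", "CD8", "B220", "NK1.1"])


@pytest.fixture
def sample(vocab):
    rng = np.random.default_rng(42)
    return CytometrySample(rng.normal(0.5, 0.2, size=(30, 3)),
                           ["CD3", "CD8", "NK1.1"], sample_id="s0",
                           label=1, batch_id="b0")


@pytest.fixture
def tiny_model(vocab):
    config = ModelConfig(hidden_size=16, encoder_layers=2, decoder_layers=2, heads=4)
    return CytoTransformer(vocab, config, n_outputs=2, seed=7)


def make_corpus(n_samples=8, n_cells=60, seed=0, vocab=None, labelled=True):
    """Tiny heterogeneous-panel corpus for unit tests (not the generator)."""
    vocab = vocab or MarkerVocabulary(["CD3", "CD4", "CD8", "B220", "NK1.1"])
    rng = np.random.default_rng(seed)
    panels = [tuple(vocab.markers), ("CD3", "CD8", "NK1.1"), ("CD3", "CD4", "B220")]
    out = []
    for i in range(n_samples):
        panel = panels[i % len(panels)]
        events = rng.normal(0.5, 0.2, size=(n_cells, len(panel)))
        out.append(CytometrySample(events, panel, sample_id=f"c{i}",
                                   label=(i % 2 if labelled else None),
                                   batch_id=f"b{i % 3}"))
    return out, vocab
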