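import numpy as np
import pytest

from boneage.model import ModelConfig
from boneage.synthetic import SyntheticSpec, canonical_layout, generate_corpus


@pytest.fixture
def canonical():
    return canonical_layout()


def micro_config(num_classes: int = 60, seed: int = 0) -> ModelConfig:
    """A minimal valid architecture for fast unit tests (14x14 working map)."""
    return ModelConfig(
        num_classes=num_classes,
        embed_channels=8,
        embed_patch=4,
        stage_depths=(1, 1),
        head_counts=(1, 2),
        window_size=7,
        seed=seed,
    )


@pytest.fixture(scope="session")
def corpus20(tmp_path_factory):
    """20-sample corpus with 6 samples reduced to 10 ROI classes."""
    out = tmp_path_factory.mktemp("corpus20")
    spec = SyntheticSpec(
        n_samples=20, dropout_fraction=0.3, dropout_keep=10, seed=7
    )
    records, truths = generate_corpus(spec, out)
    return out, records, truths


def random_stack(rng: np.random.Generator) -> np.ndarray:
    return rng.random((18, 58, 58))
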