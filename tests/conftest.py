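import numpy as np
import pytest

from metabotree.config import EvalConfig, PipelineConfig, StageConfig
from metabotree.dimred import TSNEConfig
from metabotree.nnet import MLPConfig
from metabotree.synthetic import SyntheticSpec, generate_hierarchical_dataset


def fast_config(seed: int = 1, **overrides) -> PipelineConfig:
    """Desk-scale pipeline config: small net, short t-SNE, k=20."""
    kwargs = dict(
        select_k=20,
        stage1=StageConfig(tsne=TSNEConfig(n_iter=300, perplexity=10)),
        stage2=StageConfig(tsne=TSNEConfig(n_iter=300, perplexity=10)),
        mlp=MLPConfig(hidden_sizes=(32, 32), epochs=150),
        eval=EvalConfig(seed=seed),
    )
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


@pytest.fixture
def fast_cfg():
    return fast_config()


@pytest.fixture(scope="session")
def shells_data():
    """Default 125-row hierarchical dataset (shells top split), seed 1."""
    table, data = generate_hierarchical_dataset(SyntheticSpec(seed=1))
    return table, data


@pytest.fixture
def rng():
    return np.random.default_rng(42)
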