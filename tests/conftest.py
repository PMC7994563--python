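import numpy as np
import pytest
from hypothesis import settings

from eamem import GeneratorConfig

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from eamem.datasets import feature_columns, generate_corpus, partition


@pytest.fixture(scope="session")
def small_cfg():
    """A fast 10-class corpus (100 per class) for structural tests."""
    return GeneratorConfig(n_per_class=100, seed=3)


@pytest.fixture(scope="session")
def small_splits(small_cfg):
    corpus = partition(generate_corpus(small_cfg), small_cfg.fractions,
                       fold=0, seed=small_cfg.seed + 1)
    cols = feature_columns(corpus)
    out = {}
    for name in ("train", "rem", "test"):
        part = corpus[corpus["split"] == name]
        out[name] = (part[cols].to_numpy(float), part["label"].to_numpy())
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_relation(rng, n_args, n_levels, density=0.4):
    from eamem import Relation
    return Relation(n_args, n_levels, rng.random((n_levels, n_args)) < density)


def random_function(rng, n_args, n_levels, p_assigned=0.8):
    from eamem import DiscreteFunction
    assigned = rng.random(n_args) < p_assigned
    levels = rng.integers(0, n_levels, size=n_args)
    return DiscreteFunction.from_arrays(np.where(assigned, levels, 0),
                                        assigned, n_levels)
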