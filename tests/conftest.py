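import numpy as np
import pytest

from netpropel import SyntheticSpec, build_shards, gen_planted_partition


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def planted():
    """Default planted-partition graph with module labels."""
    return gen_planted_partition(SyntheticSpec())


@pytest.fixture
def shard_factory(tmp_path):
    """Build a shard store for a graph in a fresh subdirectory."""
    counter = {"k": 0}

    def factory(graph, K):
        counter["k"] += 1
        return build_shards(graph, K, tmp_path / f"s{counter['k']}")

    return factory
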