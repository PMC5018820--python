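import numpy as np
import pytest

from reciprobots.arena import ArenaConfig
from reciprobots.controller import NetworkTopology
from reciprobots.genome import DecodingSpec, Genome, random_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def spec():
    return DecodingSpec()


@pytest.fixture
def topology():
    return NetworkTopology()


@pytest.fixture
def memory_topology():
    return NetworkTopology(has_memory=True)


@pytest.fixture
def zero_genome(spec):
    """All-zero bits decode to weight_min everywhere -- but for controller
    tests the useful motionless robot is the *uniform* genome below."""
    return Genome(np.zeros(spec.n_bits, dtype=np.uint8), spec)


@pytest.fixture
def motionless_genome():
    """A genome decoding to all-zero weights (range [0, 5], all-zero bytes):
    every unit outputs sigmoid(0) = 0.5, hence zero wheel velocity."""
    spec = DecodingSpec(weight_min=0.0, weight_max=5.0)
    return Genome(np.zeros(spec.n_bits, dtype=np.uint8), spec)


@pytest.fixture
def random_genome_182(spec, rng):
    return random_genome(spec, rng)


@pytest.fixture
def short_arena():
    """Arena with short evaluations for fast behavioral tests."""
    return ArenaConfig(eval_steps=2000)
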