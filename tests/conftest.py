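from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from kescan.phantom import NoiseModel, ParticlePopulation, PhantomSpec, build_root_phantom


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Desk-scale phantom spec used by most unit tests."""
    return PhantomSpec(shape=(16, 96, 96), seed=1234)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    """Noise-free, unshifted phantom triple (below, above, truth)."""
    return build_root_phantom(small_spec)


@pytest.fixture(scope="session")
def default_phantom():
    """The full default-size noise-free phantom (64x256x256)."""
    return build_root_phantom(PhantomSpec(seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(99)
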