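"""Shared fixtures: a small fast phantom spec and pre-generated animals.

The small spec keeps the default field of view (24 mm) on a coarser 64-voxel
grid so unit tests run in seconds; the default 96-voxel spec is reserved for
the acceptance-level end-to-end checks.
"""

import numpy as np
import pytest

from fibropet import PhantomSpec, generate_animal
from fibropet.phantom import PhantomEngine


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(shape=(64, 64, 64), spacing_mm=(0.375, 0.375, 0.375))


@pytest.fixture(scope="session")
def small_engine(small_spec) -> PhantomEngine:
    return PhantomEngine(small_spec)


@pytest.fixture(scope="session")
def blm_animal(small_spec, small_engine):
    """One bleomycin animal, all four sessions, deterministic."""
    return generate_animal(small_spec, "BLM", 42, engine=small_engine)


@pytest.fixture(scope="session")
def nacl_animal(small_spec, small_engine):
    return generate_animal(small_spec, "NaCl", 7, engine=small_engine)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
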