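from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rdnaquant.formats_io import RdnaUnitReference
from rdnaquant.synthetic_data import default_reference, random_unit

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def unit600() -> RdnaUnitReference:
    """A small unit for alignment-level tests."""
    return RdnaUnitReference(unit=random_unit(600, seed=42))


@pytest.fixture(scope="session")
def ref6k() -> RdnaUnitReference:
    """Full-size 6 kb unit with the default subregion annotation."""
    return default_reference(6000, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def mutate(seq: str, positions, rng=None) -> str:
    """Substitute (cyclic base shift) at the given positions."""
    flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
    s = list(seq)
    for p in positions:
        s[p] = flip[s[p]]
    return "".join(s)
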