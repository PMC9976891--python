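import numpy as np
import pytest
from hypothesis import settings

from sdscan.duplex_energy import NNParameterTable
from sdscan.synthetic_data import build_organism, flavobacteriales_like_spec

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return NNParameterTable.default()


@pytest.fixture(scope="session")
def flavo(params):
    """One Flavobacteriales-like organism with its truth table (seed 1)."""
    return build_organism(flavobacteriales_like_spec(seed=1), params)


def random_rna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(["A", "C", "G", "U"], size=n, p=probs))
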