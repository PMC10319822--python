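import numpy as np
import pytest
from hypothesis import settings

from lossweb import ContactData, NormalizedMatrix

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


def make_contacts(wins, draws=None, abundance=None, species=None, assemblage_id="test"):
    wins = np.asarray(wins)
    s = wins.shape[0]
    if draws is None:
        draws = np.zeros((s, s), dtype=int)
    if abundance is None:
        abundance = np.full(s, 10)
    if species is None:
        species = [chr(ord("A") + k) for k in range(s)]
    return ContactData(assemblage_id, species, wins, draws, abundance)


def random_normalized(rng, s=6, connectance=1.0, sigma=0.8, reciprocal=True):
    """Random competition matrix with uniform diagonal -1 as a NormalizedMatrix."""
    a = -np.abs(rng.normal(0.0, sigma, (s, s)))
    a[np.abs(a) < 1e-3] = -1e-3  # keep active links clearly non-zero
    for i in range(s):
        for j in range(i + 1, s):
            if rng.random() >= connectance:
                a[i, j] = a[j, i] = 0.0
    if not reciprocal:
        # knock out a few one-sided links
        for i in range(s):
            for j in range(s):
                if i != j and a[i, j] != 0 and rng.random() < 0.15:
                    a[i, j] = 0.0
    np.fill_diagonal(a, -1.0)
    return NormalizedMatrix([f"sp{k}" for k in range(s)], a)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
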