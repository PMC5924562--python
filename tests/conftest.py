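import numpy as np
import pytest

from mitodem.sumstats import TemporalAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)


def make_alignment(seqs, layers=None, ages=None, ids=None):
    """Build a TemporalAlignment from a list of equal-length strings."""
    n = len(seqs)
    layers = layers or ["modern"] * n
    if ages is None:
        ages = {layer: 0.0 for layer in set(layers)}
        if "historical" in ages:
            ages["historical"] = 5.0
    ids = ids or [f"s{i}" for i in range(n)]
    matrix = np.array([list(s) for s in seqs], dtype="S1")
    return TemporalAlignment(matrix=matrix, ids=ids, layers=layers, ages=ages)


def random_alignment(rng, n, length, layers=None, n_fraction=0.0):
    """Random ACGT alignment, optionally salted with missing data."""
    bases = np.array(list("ACGT"))
    mat = bases[rng.integers(0, 4, size=(n, length))]
    if n_fraction > 0:
        mask = rng.random((n, length)) < n_fraction
        mat[mask] = "N"
    return make_alignment(["".join(row) for row in mat], layers=layers)
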