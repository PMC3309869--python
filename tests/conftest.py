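import numpy as np
import pytest

from rvjoint import BINARY, CONTINUOUS, GenotypeMatrix, PhenotypeVector


def make_genotypes(counts) -> GenotypeMatrix:
    counts = np.asarray(counts)
    n, m = counts.shape
    return GenotypeMatrix([f"S{i}" for i in range(n)],
                          [f"V{j}" for j in range(m)], counts)


def random_instance(rng, n, m, trait=CONTINUOUS, maf=(0.05, 0.3)):
    """A small dense genotype/phenotype pair for oracle tests."""
    freqs = rng.uniform(*maf, size=m)
    counts = rng.binomial(2, freqs, size=(n, m)).astype(np.int16)
    G = make_genotypes(counts)
    if trait == CONTINUOUS:
        y = PhenotypeVector(rng.standard_normal(n), CONTINUOUS)
    else:
        vals = rng.binomial(1, 0.5, size=n).astype(float)
        while vals.min() == vals.max():
            vals = rng.binomial(1, 0.5, size=n).astype(float)
        y = PhenotypeVector(vals, BINARY)
    return y, G


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
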