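import numpy as np
import pandas as pd
import pytest

from clinescan.datatypes import GeneAnnotation, GenotypeTable
from clinescan.simulate import SimConfig, simulate_dataset


def make_table(calls, chrom="chr1", start=100, step=100, sample_prefix="s"):
    """Small GenotypeTable around an explicit call matrix."""
    calls = np.asarray(calls, dtype=np.int16)
    n, m = calls.shape
    sites = pd.DataFrame({
        "chrom": [chrom] * m,
        "pos": [start + j * step for j in range(m)],
        "ref": ["A"] * m,
        "alt": ["G"] * m,
    })
    return GenotypeTable([f"{sample_prefix}{i}" for i in range(n)], sites, calls)


def random_table(rng, n=10, m=50, missing_rate=0.1):
    calls = rng.integers(0, 3, size=(n, m)).astype(np.int16)
    if missing_rate:
        calls[rng.random(calls.shape) < missing_rate] = -1
    return make_table(calls)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """One shared small synthetic dataset for cross-module tests."""
    cfg = SimConfig(seed=7, n_sites=800, n_genes=80, n_transects=2)
    return simulate_dataset(cfg)


@pytest.fixture
def toy_genes():
    return [
        GeneAnnotation("gA", "chr1", 1000, 2000,
                       [(1000, 1200), (1500, 2000)], "+"),
        GeneAnnotation("gB", "chr1", 1800, 2600, [(1800, 2600)], "-"),
        GeneAnnotation("gC", "chr2", 500, 900, [(500, 900)], "+"),
    ]
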