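import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from trigene.datatypes import GenotypeMatrix, PopulationMap


def make_matrix(genotypes, chrom="1", start_pos=100, spacing=1000, cm_per_kb=0.001,
                samples=None, depth=None):
    """Build a GenotypeMatrix from a (variants x samples) array of {-1,0,1,2}."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_var, n_samp = g.shape
    if samples is None:
        samples = [f"S{j:03d}" for j in range(n_samp)]
    pos = start_pos + spacing * np.arange(n_var)
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "aa": "A",
            "cm": (pos / 1000.0) * cm_per_kb if cm_per_kb is not None else np.nan,
            "depth": depth if depth is not None else np.nan,
        }
    )
    return GenotypeMatrix(variants, samples, g)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def two_pop_dataset():
    """Small two-population split dataset reused across tests."""
    from trigene.demography import two_population_model
    from trigene.simdata import default_popmap, simulate_neutral

    model = two_population_model(
        n_anc=150, n_a=150, n_b=150, split_time=60,
        mutation_rate=2e-6, recombination_rate=0.0, rescale_factor=1.0,
    )
    n = {"A": 12, "B": 12}
    geno = simulate_neutral(model, n, region_lengths=[8000] * 40, seed=101, burnin=120)
    return geno, default_popmap(n)


def random_genotype_pair(rng, max_sites=10, max_n=12):
    """Random genotype arrays for two populations (with some missing calls)."""
    s = rng.integers(1, max_sites + 1)
    n1 = rng.integers(2, max_n + 1)
    n2 = rng.integers(2, max_n + 1)
    ga = rng.integers(0, 3, size=(s, n1)).astype(np.int8)
    gb = rng.integers(0, 3, size=(s, n2)).astype(np.int8)
    miss_a = rng.random((s, n1)) < 0.1
    miss_b = rng.random((s, n2)) < 0.1
    ga[miss_a] = -1
    gb[miss_b] = -1
    return ga, gb
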