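import numpy as np
import pandas as pd
import pytest

from microscca import FeatureTable, GenotypeMatrix, SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    """Random 20 x 12 raw count table with lengths."""
    vals = rng.poisson(5.0, size=(20, 12)).astype(float)
    vals[0, :3] = 0.0
    ids = [f"K{i:03d}" for i in range(20)]
    samples = [f"S{j}" for j in range(12)]
    lengths = pd.Series(rng.integers(300, 3000, 20), index=ids)
    return FeatureTable(pd.DataFrame(vals, index=ids, columns=samples), lengths=lengths)


@pytest.fixture
def small_cohort():
    """Small planted cohort for residualization and pipeline wiring tests."""
    cfg = SimulationConfig(
        n_pairs=60, n_loci=120, n_features=80,
        n_planted_snp_groups=3, n_planted_features=8, seed=424242,
    )
    return simulate_cohort(cfg)


def make_genotypes(calls: np.ndarray, chrom=None, pos=None) -> GenotypeMatrix:
    """Helper: wrap a calls array (samples x loci) as a GenotypeMatrix."""
    n, L = calls.shape
    loci_ids = [f"rs{j}" for j in range(L)]
    loci = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * L,
            "pos": pos if pos is not None else np.arange(L),
        },
        index=loci_ids,
    )
    samples = [f"S{i:03d}" for i in range(n)]
    return GenotypeMatrix(pd.DataFrame(calls, index=samples, columns=loci_ids), loci)
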