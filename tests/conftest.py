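import numpy as np
import pandas as pd
import pytest

from nampop import (GenomeModel, GenotypeMatrix, SimConfig, simulate_founders,
                    simulate_nam)


@pytest.fixture(scope="session")
def small_genome():
    return GenomeModel.regular(n_chromosomes=2, chrom_length_bp=100_000_000,
                               chrom_length_cm=100.0, markers_per_chromosome=50)


@pytest.fixture(scope="session")
def founder_panel(small_genome):
    return simulate_founders(small_genome, n_founders=5, divergence=0.6, seed=42)


@pytest.fixture(scope="session")
def small_nam(small_genome, founder_panel):
    sim = SimConfig(n_families=4, rils_per_family=40, seed=42,
                    missing_rate=0.0, het_error_rate=0.0, ascertainment_fraction=0.0)
    return simulate_nam(founder_panel, small_genome, sim)


def genotypes_from_codes(codes, families=None, sample_prefix="s", marker_prefix="m"):
    """Build a GenotypeMatrix from a plain int array (test helper)."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    fams = families if families is not None else ["f1"] * n
    return GenotypeMatrix(codes,
                          [f"{sample_prefix}{i:03d}" for i in range(n)],
                          [f"{marker_prefix}{j:03d}" for j in range(m)],
                          fams)
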