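import numpy as np
import pandas as pd
import pytest

from mcqtl.io import GeneticMap
from mcqtl.simpop import simulate_preset
from mcqtl.studies import simulate_study_population


@pytest.fixture
def tiny_map():
    """Three markers on chromosome 5A at 0/10/20 cM."""
    return GeneticMap(pd.DataFrame({
        "marker_id": ["m1", "m2", "m3"],
        "chromosome": ["5A", "5A", "5A"],
        "position_cM": [0.0, 10.0, 20.0],
    }))


@pytest.fixture(scope="session")
def small_population():
    """Four families x 30 lines on a 2-chromosome map (no QTL attached)."""
    rng = np.random.default_rng(1234)
    geno, _ = simulate_study_population(rng, sizes=(30,) * 4, n_chrom=2,
                                        n_markers=12)
    return geno


@pytest.fixture(scope="session")
def power_population():
    """Four families x 125 lines, 200 markers on two chromosomes."""
    rng = np.random.default_rng(99)
    geno, _ = simulate_study_population(rng, sizes=(125,) * 4, n_chrom=2,
                                        n_markers=100)
    return geno


@pytest.fixture(scope="session")
def mini_preset():
    """One realisation of the reduced-scale paired-trait preset."""
    return simulate_preset("triticale_mini", seed=7)
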