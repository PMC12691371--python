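import numpy as np
import pandas as pd
import pytest

from dualscreen import (
    CountTable,
    GuideLibrary,
    build_dual_design,
    make_screen_design,
    make_synthetic_library,
)
from dualscreen import simulate as sim


@pytest.fixture
def tiny_library() -> GuideLibrary:
    """3 genes x 2 guides + 2 safe guides (8 guides total)."""
    return make_synthetic_library(3, guides_per_gene=2, n_safe=2, gene_prefix="T")


@pytest.fixture(scope="session")
def noiseless_cdko():
    """Small noiseless dual-knockout screen with 2 planted interactions."""
    return sim.default_cdko_scenario(
        seed=1, n_genes=6, n_safe=3, n_planted=2, noiseless=True
    )


@pytest.fixture(scope="session")
def noisy_cdko_small():
    """12-gene dual-knockout screen at the default (moderate) noise."""
    return sim.default_cdko_scenario(seed=2, n_genes=12, n_safe=4, n_planted=3)


@pytest.fixture(scope="session")
def cohort_small():
    """Compact patient cohort + cell-line panel with planted truth."""
    truth = sim.make_cohort_truth(n_genes=400, n_deg=60, seed=5)
    matrix, truth = sim.simulate_transcriptome_cohort(
        truth, n_responders=8, n_nonresponders=12, n_genes=400, seed=5
    )
    sets = sim.make_hallmark_like_sets(
        matrix.genes, n_sets=12, set_size=20, deg_genes=truth.deg_delta.index,
        n_deg_sets=4, seed=5
    )
    return matrix, truth, sets


@pytest.fixture
def simple_counts() -> CountTable:
    rng = np.random.default_rng(0)
    frame = pd.DataFrame(
        rng.integers(10, 1000, size=(20, 4)),
        index=[f"g{i}" for i in range(20)],
        columns=["T0_1", "T0_2", "Tend_cis_1", "Tend_cis_2"],
    )
    return CountTable(frame)


@pytest.fixture
def simple_design():
    return make_screen_design(conditions=("drug:cis",), n_replicates=2, n_t0=2)
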