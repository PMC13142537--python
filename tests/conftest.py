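import numpy as np
import pandas as pd
import pytest

import tautraj as tt


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-cell, 200-protein cohort with all response classes present."""
    cfg = tt.CohortConfig(n_cells=60, n_proteins=200, seed=1)
    matrix, truth = tt.generate_cohort(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def imputed_cohort(small_cohort):
    cfg, matrix, truth = small_cohort
    m = tt.inject_missingness(matrix, cfg)
    m = tt.impute_downshifted_normal(m, seed=5)
    return cfg, m, truth


@pytest.fixture()
def toy_matrix():
    """Tiny handmade matrix with known missingness."""
    vals = pd.DataFrame(
        {
            "S1": [14.0, 20.0, np.nan, 16.0],
            "S2": [15.0, np.nan, 12.0, 17.0],
            "S3": [16.0, 21.0, 13.0, np.nan],
        },
        index=["MAPT", "Cont_KRT1", "SQSTM1", "PSMA1"],
    )
    samples = tt.make_sample_table(
        ["S1", "S2", "S3"], ["D1", "D1", "D2"],
        ["negative", "positive", "positive"],
    )
    return tt.from_values(vals, samples)
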