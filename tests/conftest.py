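import numpy as np
import pandas as pd
import pytest

from pimsel import methylome_io, synthetic_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort shared by read-only tests."""
    cfg = synthetic_cohort.CohortConfig(
        n_patients=20, n_promoters=60, cpgs_per_promoter=4,
        n_background_cpgs=300, seed=42)
    return synthetic_cohort.generate_cohort(cfg)


@pytest.fixture()
def toy_matrix():
    """4 embryos x 3 promoters with one missing cell; labels alongside."""
    vals = pd.DataFrame(
        [[0.20, 0.50, 0.10],
         [0.30, 0.55, np.nan],
         [0.25, 0.45, 0.12],
         [0.60, 0.50, 0.11]],
        index=pd.Index(["B1", "B2", "B3", "F1"], name="embryo_id"),
        columns=["g1", "g2", "g3"])
    cov = vals.notna().astype(int) * 100
    matrix = methylome_io.PromoterMatrix(vals, cov, min_coverage=30)
    labels = pd.Series(["Birth", "Birth", "Birth", "Failed"],
                       index=vals.index, name="outcome")
    return matrix, labels
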