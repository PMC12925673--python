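import numpy as np
import pytest

import idmrates as m


@pytest.fixture(scope="session")
def truth():
    """Default synthetic study truth (shared across tests; read-only)."""
    return m.default_truth()


@pytest.fixture(scope="session")
def female_anxiety(truth):
    return truth.stratum("female", "anxiety")


@pytest.fixture(scope="session")
def smooth_curves(female_anxiety):
    """Log-linear mortality and MRR curves fitted to the truth's tables."""
    mc = m.fit_log_mortality(female_anxiety.mortality_table("female"))
    rc = m.fit_mrr(female_anxiety.mrr_table("anxiety"))
    return mc, rc


@pytest.fixture(scope="session")
def hamburg_grid():
    return m.EvaluationGrid(sex="female", center="Hamburg")


@pytest.fixture(scope="session")
def small_study(truth):
    """One-center sampled study, modest n — shared by several test modules."""
    return m.sample_study(truth, 6000, centers=["Hamburg"], seed=20240901)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
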