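import numpy as np
import pytest

import shashnorm as sn


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_cohort():
    """A 3-site cohort simulated from the Sb1 generative process."""
    cfg = sn.SimConfig(
        n_sites=3, n_per_site=60, epsilon=0.3, delta=1.2,
        w_mu=np.array([0, 0, 0, 0, 0, 0.02, 0.2]), seed=17,
    )
    return sn.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_design(small_cohort):
    df = small_cohort.table
    X, knots = sn.build_design_matrix(
        df["age"].to_numpy(), df["sex"].to_numpy(), knots=small_cohort.knots
    )
    batch = df["site"].str[-2:].astype(int).to_numpy()
    return X, batch, df["response"].to_numpy()
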