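import numpy as np
import pandas as pd
import pytest

from gardenhunt.survey import standardize


def make_covariates(M: int = 54, seed: int = 0) -> pd.DataFrame:
    """Standardized site-covariate table shaped like the study landscape:
    bimodal tree cover, lognormal distances, mild track-density signal."""
    rng = np.random.default_rng(seed)
    half = M // 2
    tree = np.r_[rng.normal(15, 4, half), rng.normal(75, 6, M - half)]
    return pd.DataFrame(
        {
            "camera_id": [f"C{i:02d}" for i in range(M)],
            "tree_buffer": standardize(tree),
            "dist_river": standardize(rng.lognormal(6.3, 0.8, M)),
            "dist_conuco": standardize(rng.lognormal(6.865, 1.0, M)),
            "track_dens": standardize(rng.normal(0, 1, M)),
        }
    )


@pytest.fixture
def std_covariates() -> pd.DataFrame:
    return make_covariates()


@pytest.fixture(scope="session")
def study_tables():
    """One deterministic synthetic study shared across tests."""
    from gardenhunt.simulate import default_truth, simulate_study

    truth = default_truth(seed=7)
    return truth, simulate_study(truth)
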