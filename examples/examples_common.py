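"""Shared helper for the example scripts."""

import numpy as np
import pandas as pd

from gardenhunt.survey import standardize


def study_covariates(M: int = 54, seed: int = 0) -> pd.DataFrame:
    """Standardized site covariates shaped like the study landscape."""
    rng = np.random.default_rng(seed)
    half = M // 2
    return pd.DataFrame(
        {
            "camera_id": [f"C{i:02d}" for i in range(M)],
            "tree_buffer": standardize(
                np.r_[rng.normal(15, 4, half), rng.normal(75, 6, M - half)]
            ),
            "dist_river": standardize(rng.lognormal(6.3, 0.8, M)),
            "dist_conuco": standardize(rng.lognormal(6.865, 1.0, M)),
            "track_dens": standardize(rng.normal(0, 1, M)),
        }
    )
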