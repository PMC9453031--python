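import numpy as np
import pandas as pd
import pytest

from mal_profiler.synthetic import FixtureSpec, plant_fixture
from mal_profiler.territories import Territory

#: printed per-territory (single, multiple) patient counts of the cohort table
TERRITORY_CELLS = {
    Territory.ACA_LEFT: (22, 17),
    Territory.ACA_RIGHT: (25, 19),
    Territory.MCA_LEFT: (476, 469),
    Territory.MCA_RIGHT: (422, 427),
    Territory.PCA_LEFT: (108, 109),
    Territory.PCA_RIGHT: (110, 85),
    Territory.CEREBELLUM_LEFT: (93, 81),
    Territory.CEREBELLUM_RIGHT: (82, 100),
    Territory.BRAINSTEM: (276, 61),
}

#: constellation-category and flag counts of the published 2,466-patient cohort
COHORT_CATEGORY_COUNTS = {
    "single_in_one": 1225,
    "multiple_in_one": 922,
    "two_singles": 79,
    "single_plus_multiple": 102,
    "two_multiples": 138,
}
COHORT_FLAG_COUNTS = {"bilateral": 196, "supra_and_infra": 138, "ant_and_post": 46}


@pytest.fixture(scope="session")
def published_cohort_fixture() -> pd.DataFrame:
    """Planted cohort reproducing the published category/flag counts exactly."""
    return plant_fixture(
        FixtureSpec(categories=dict(COHORT_CATEGORY_COUNTS), flags=dict(COHORT_FLAG_COUNTS))
    )


@pytest.fixture(scope="session")
def territory_table_fixture() -> pd.DataFrame:
    """Planted cohort reproducing every printed per-territory cell exactly."""
    return plant_fixture(FixtureSpec(territory_cells=dict(TERRITORY_CELLS)))


def make_linear_frame(seed, n_per_group, beta_single, beta_multiple, sigma, alpha=2.0):
    """Synthetic regression data with known group slopes on log volume."""
    rng = np.random.default_rng(seed)
    v = rng.lognormal(1.0, 1.2, 2 * n_per_group)
    x = np.log(np.clip(v, 0.01, None))
    grp = np.repeat([False, True], n_per_group)
    beta = np.where(grp, beta_multiple, beta_single)
    y = alpha + beta * x + rng.normal(0.0, sigma, 2 * n_per_group)
    return pd.DataFrame({"nihss": y, "dwi_vol_ml": v, "mal": grp})


def make_logistic_frame(seed, n_per_group, beta_single, beta_multiple, alpha=-1.0):
    from scipy.special import expit

    rng = np.random.default_rng(seed)
    v = rng.lognormal(1.0, 1.2, 2 * n_per_group)
    x = np.log(np.clip(v, 0.01, None))
    grp = np.repeat([False, True], n_per_group)
    beta = np.where(grp, beta_multiple, beta_single)
    y = (rng.random(2 * n_per_group) < expit(alpha + beta * x)).astype(float)
    return pd.DataFrame({"mrs_gt2": y, "dwi_vol_ml": v, "mal": grp})
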