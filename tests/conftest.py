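import numpy as np
import pytest

import spotnmix as sx


@pytest.fixture(scope="session")
def small_design():
    """10 transects x 6 seasons, realistic lengths, some missingness."""
    return sx.make_survey_design(10, 6, 23.1, 5.9, 0.15, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    cfg = sx.default_config(small_design, seed=42)
    counts, truth = sx.simulate_dataset(small_design, cfg)
    return counts, truth


@pytest.fixture(scope="session")
def tiny_prey_fit():
    """A quick prey-only fit reused by several diagnostic tests."""
    design = sx.make_survey_design(5, 4, 23.1, 5.9, 0.0, seed=7)
    cfg = sx.default_config(design, seed=7)
    counts, _ = sx.simulate_dataset(design, cfg)
    data = sx.CountData(y={"rabbit": counts.y["rabbit"]},
                        lengths_km=counts.lengths_km,
                        season_type=counts.season_type)
    model = sx.NumericalResponseModel(data)
    return model.fit(n_chains=2, n_iter=1500, burn_in=500, thin=2, seed=5)
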