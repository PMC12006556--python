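import warnings

import numpy as np
import pandas as pd
import pytest

import trialcea as tc


@pytest.fixture(scope="session")
def trial_data():
    """One synthetic trial at the study's default size (75 per arm)."""
    cfg = tc.TrialConfig(seed=20190507 % 2**31)
    return tc.generate_trial(cfg)


@pytest.fixture(scope="session")
def analysis_inputs(trial_data):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tc.prepare_analysis(trial_data)


@pytest.fixture(scope="session")
def fitted_models(analysis_inputs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tc.fit_models(analysis_inputs)


def random_patients(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Covariate table for simulation studies (both arms, realistic ranges)."""
    return pd.DataFrame(
        {
            "patient_id": [f"S{i:05d}" for i in range(n)],
            "arm": rng.choice(["swab", "tissue"], n),
            "age": rng.normal(62.7, 12.0, n).clip(18, 100),
            "sex": rng.choice(["male", "female"], n, p=[0.83, 0.17]),
            "n_ulcers": 1 + rng.poisson(0.3, n),
            "ulcer_area": rng.lognormal(0.4, 1.3, n),
            "ulcer_duration": rng.lognormal(0.3, 1.4, n),
        }
    )
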