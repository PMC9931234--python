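import numpy as np
import pandas as pd
import pytest

from illdyn.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A linked 40-admission cohort with positive entropy-outcome links."""
    outdir = tmp_path_factory.mktemp("cohort")
    config = CohortConfig(
        n_admissions=40,
        seed=7,
        mortality_link=(-2.3, 0.6),
        outcome_link=0.6,
        gap_rate=0.003,
        duration_days_range=(2.0, 14.0),
    )
    paths = generate_cohort(config, outdir)
    return {
        "config": config,
        "paths": paths,
        "scores": pd.read_csv(paths["scores"], comment="#"),
        "outcomes": pd.read_csv(paths["outcomes"], comment="#"),
        "truth": pd.read_csv(paths["truth"], comment="#"),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
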