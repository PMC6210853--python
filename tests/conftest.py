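import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from hccmolrisk.simulate import GeneratorConfig, generate_cohort

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-sample simulated cohort with its ground truth (fixed seed)."""
    return generate_cohort(GeneratorConfig(n=60, seed=11))


@pytest.fixture(scope="session")
def medium_cohort():
    """A 500-sample simulated cohort for recovery properties (fixed seed)."""
    return generate_cohort(GeneratorConfig(n=500, seed=0))


@pytest.fixture()
def feature_frame():
    """A tiny hand-built feature table covering all six flags."""
    return pd.DataFrame(
        {
            "ctnnb1_mut": [False, True, False, True],
            "tp53_mut": [True, False, True, False],
            "tertp_mut": [True, True, False, False],
            "tsg_hyper": [True, False, True, False],
            "global_hypo": [True, False, False, True],
            "fal_high": [True, False, True, False],
            "fal_percent": [45.0, 8.0, 30.0, 12.0],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
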