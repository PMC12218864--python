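import warnings

import numpy as np
import pandas as pd
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from invade.synthetic import TrueParameters, generate_design, simulate_site_covariates


@pytest.fixture(scope="session")
def small_design():
    return generate_design(n_squares_s1=10, n_squares_s2=4, days=15, seed=42)


@pytest.fixture(scope="session")
def default_params():
    return TrueParameters()


@pytest.fixture(scope="session")
def small_sites(small_design, default_params):
    return simulate_site_covariates(small_design, default_params, seed=42)
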