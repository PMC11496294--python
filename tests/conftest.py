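import numpy as np
import pytest

import dmtpower as dp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_trial():
    """A modest 1-year quarterly trial reused by several LMM tests."""
    design = dp.make_design("clinic_quarterly", 1.0)
    from dataclasses import replace

    params = replace(dp.MDS_UPDRS_PARAMS, effect=0.7)
    return dp.simulate_trial(design, params, 40, seed=7)
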