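import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """One subject's 378-trial synthetic session (auditory, fixed seed)."""
    from tremortime import synthetic_data as sd

    design = sd.DesignConfig(n_subjects=1, seed=7)
    observer = sd.ObserverConfig()
    return sd.generate_dataset(
        design, observer, modality="auditory", rng=np.random.default_rng(7)
    )


def gumbel_bp_cv(m, s):
    """Closed-form BP and CV of the cumulative Gumbel (test oracle)."""
    bp = 10 ** (m + s * np.log(np.log(2.0)))
    q75 = 10 ** (m + s * np.log(-np.log(0.25)))
    q25 = 10 ** (m + s * np.log(-np.log(0.75)))
    return bp, (q75 - q25) / (2 * bp)
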