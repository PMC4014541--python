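import numpy as np
import pytest

import bolusflux as bf


@pytest.fixture(scope="session")
def schedule():
    return bf.default_schedule()


@pytest.fixture(scope="session")
def dose():
    """The standard 3 mg/kg [1-13C]glutamine bolus."""
    return bf.TracerDose()


@pytest.fixture()
def mono_curve(schedule):
    """Noiseless default-parameter single-pool curve with its ground truth."""
    params = bf.PoolModelParams()
    return bf.simulate_single_pool(params, schedule)


def mono_exp_auc(amplitude, k, t_start, t_end):
    """Closed-form integral of amplitude * exp(-k t) — the independent AUC oracle."""
    return amplitude * (np.exp(-k * t_start) - np.exp(-k * t_end)) / k
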