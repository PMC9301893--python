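"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pytest

from vratio import DDMParams, generate_confidence_rt_pool, simulate_dataset
from vratio.confidence import ConfidenceScaleSpec


@pytest.fixture(scope="session")
def six_point():
    return ConfidenceScaleSpec.six_point()


@pytest.fixture(scope="session")
def small_dataset(six_point):
    """200 trials from a mid-range parameter set, six-point scale."""
    params = DDMParams(drift_v=2.0, boundary_a=1.5, ter=0.4, v_ratio=0.7,
                       conf_M=2.5, conf_SD=1.2)
    rng = np.random.default_rng(2024)
    pool = generate_confidence_rt_pool(params, 500, rng)
    ds = simulate_dataset(params, 200, pool, rng, scale_spec=six_point, subject="s1")
    return params, ds
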