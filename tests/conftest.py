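import numpy as np
import pandas as pd
import pytest

from survstc import IPDDataset, generate_ipd


@pytest.fixture
def tiny_ipd():
    """Four subjects, all events, no covariates (closed-form exponential MLE)."""
    return IPDDataset(
        time=np.array([1.0, 2.0, 3.0, 4.0]),
        event=np.array([1, 1, 1, 1]),
        covariates=pd.DataFrame(index=range(4)),
    )


@pytest.fixture(scope="session")
def weibull_binary_data():
    """n=300 Weibull AFT with one binary covariate (beta=0.7), ~20% censored."""
    return generate_ipd(
        family="weibull",
        params={"mu": -3.0, "shape": 1.3},
        beta={"x": 0.7},
        covariate_model={"x": ("bernoulli", 0.4)},
        n=300,
        censoring=(30.0, 0.01),
        seed=5,
    )


@pytest.fixture(scope="session")
def exp_arm():
    """n=400 exponential(0.05) arm with mixed censoring, for KM/Guyot tests."""
    return generate_ipd(
        family="exponential",
        params={"mu": np.log(0.05)},
        n=400,
        censoring=(48.0, 0.015),
        seed=11,
        arm_label="comparator",
    )
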