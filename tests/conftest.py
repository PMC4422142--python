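import numpy as np
import pytest
from hypothesis import settings

from distprop import GroupSummary, Threshold

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20150424)


@pytest.fixture
def birthweight_summaries():
    """Low-birthweight worked example: smokers vs non-smokers, cut 2500 g."""
    return {
        "exposed": GroupSummary("smoker", 494, 3267.0, 441.0),
        "reference": GroupSummary("non-smoker", 983, 3452.0, 435.0),
        "threshold": Threshold(2500.0, "below"),
    }


@pytest.fixture
def inverse_bmi_summaries():
    """Obesity (BMI > 30) worked example on the inverse-BMI scale."""
    return {
        "exposed": GroupSummary("multipari", 890, 0.0430, 0.0062),
        "reference": GroupSummary("primipari", 891, 0.0444, 0.0059),
    }
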