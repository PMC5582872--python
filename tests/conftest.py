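import numpy as np
import pytest

from updown.core import StateIntervals
from updown.ratenet import GREEN_SQUARE, RateModelParams


@pytest.fixture(scope="session")
def green_square() -> RateModelParams:
    """Rate-model parameters of the fitted bistable example point."""
    return GREEN_SQUARE


@pytest.fixture()
def simple_intervals() -> StateIntervals:
    return StateIntervals(
        states=["D", "U", "D", "U"],
        onsets=np.array([0.0, 1.0, 1.5, 2.2]),
        offsets=np.array([1.0, 1.5, 2.2, 3.0]),
    )
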