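from datetime import datetime

import numpy as np
import pytest

from actisleep import ActivityIntensitySeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240603)


@pytest.fixture
def make_series():
    """Factory for intensity series starting at a fixed evening timestamp."""

    def _make(intensities, child_id="child01", start=datetime(2024, 6, 3, 18, 0)):
        return ActivityIntensitySeries(
            child_id=child_id, start_time=start, intensities=np.asarray(intensities)
        )

    return _make
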