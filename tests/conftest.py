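import numpy as np
import pytest

from myodmi.model import TissueParams
from myodmi.synthetic import FRACTION_STATS, default_scheme


@pytest.fixture(scope="session")
def tissue():
    return TissueParams()


@pytest.fixture(scope="session")
def scheme():
    """The study's two-shell protocol: 1 b0 + 12 directions at b=600 and 1000."""
    return default_scheme()


@pytest.fixture(scope="session")
def male_truth():
    """Per-muscle ground truth at the male group means, 5% fat everywhere."""
    out = {}
    for muscle, stats in FRACTION_STATS.items():
        vi, _, vs, _ = stats["M"]
        out[muscle] = {
            "v_intra": vi,
            "v_extra": 1.0 - vi - vs,
            "v_iso": vs,
            "ff": 5.0,
        }
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
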