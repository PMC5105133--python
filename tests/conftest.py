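import numpy as np
import pandas as pd
import pytest

from lfcnet.epochs import EpochSet
from lfcnet.montage import CHANNELS


def make_epochs(data, fs=500.0, t0=-0.3, groups=None, stims=None, rts=None, clicks=None):
    """Build a valid EpochSet around a raw data cube for tests."""
    n = data.shape[0]
    meta = pd.DataFrame(
        {
            "subject": ["s1"] * n,
            "group": groups if groups is not None else ["guilty"] * n,
            "stim": stims if stims is not None else ["P"] * n,
            "rt_ms": rts if rts is not None else [400.0] * n,
            "click_ok": clicks if clicks is not None else [True] * n,
        }
    )
    return EpochSet(data=data, fs=fs, t0=t0, channel_names=CHANNELS[: data.shape[1]]
                    if data.shape[1] <= 12 else tuple(f"ch{i}" for i in range(data.shape[1])),
                    meta=meta)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def white_epoch(rng):
    """One 12-channel white-noise epoch at the standard geometry."""
    return rng.standard_normal((12, 800))
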