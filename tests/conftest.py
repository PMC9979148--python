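import numpy as np
import pandas as pd
import pytest

from flickerkit.spectral import PSDResult


@pytest.fixture
def constructed_psd():
    """PSD with hand-set neighbor statistics around 40 Hz.

    1-Hz grid over 2-100 Hz; the 18 neighbor bins (31-39, 41-49 Hz)
    alternate 10 - a and 10 + a dB with a = sqrt(17/18), giving mean
    exactly 10 dB and sample sd exactly 1 dB, so the channel z-score is
    P(40) - 10 by construction.
    """

    def build(p40_db: float, n_channels: int = 1) -> PSDResult:
        freqs = np.arange(2.0, 101.0)
        power = np.full((n_channels, len(freqs)), 10.0)
        nb = ((freqs >= 31) & (freqs <= 39)) | ((freqs >= 41) & (freqs <= 49))
        a = np.sqrt(17.0 / 18.0)
        alt = 10.0 + np.where(np.arange(nb.sum()) % 2 == 0, -a, a)
        power[:, nb] = alt
        power[:, freqs == 40.0] = p40_db
        channels = pd.DataFrame(
            {"channel_id": [f"ch{c}" for c in range(n_channels)]}
        )
        return PSDResult(freqs=freqs, power_db=power, channels=channels,
                         params={"freq_resolution": 1.0})

    return build
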