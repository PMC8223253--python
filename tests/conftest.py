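import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from scalphfo.core import EEGRecording
from scalphfo.synth import generate_background


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def background_10s() -> EEGRecording:
    """10 s of 1/f background on three channels at 1 kHz."""
    return generate_background(10.0, 1000.0, ["C3", "C4", "O1"], 20.0, seed=11)


@pytest.fixture
def background_1ch_60s() -> EEGRecording:
    return generate_background(60.0, 1000.0, ["C3"], 20.0, seed=12)
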