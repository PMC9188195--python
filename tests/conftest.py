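import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests/_oracles.py

from plaquemap import synthetic as syn


@pytest.fixture
def section_truth() -> syn.SectionTruth:
    """A noiseless section with several plaques and microglia."""
    return syn.random_section_truth(seed=11, n_plaques=4, n_microglia=10)


@pytest.fixture
def volume_truth() -> syn.VolumeTruth:
    """A noiseless volume with three well-separated somata."""
    return syn.random_volume_truth(seed=7, n_somata=3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
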