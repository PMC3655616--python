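import sys
from pathlib import Path

import numpy as np
import pytest

import eegbico as eb

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

FS = 256.0


@pytest.fixture(scope="session")
def coupled_triplet_epochs():
    """200 two-second epochs (75% overlap) of a fully coupled 6+9->15 Hz
    triplet over weak white noise, plus the raw recording."""
    n = 512 + 199 * 128  # exactly 200 epochs at 2 s / 75% overlap
    spec = eb.SynthSpec(
        n_channels=1, fs=FS, duration=n / FS, background_slope=0.0,
        background_rms=0.5, qpc_triplets=[(6.0, 9.0, 1.0, 1.0)], seed=11,
    )
    rec = eb.build_recording(spec)
    return eb.make_epochs(rec), rec


@pytest.fixture(scope="session")
def uncoupled_triplet_epochs():
    """Same triplet with independently randomized sum-component phase."""
    n = 512 + 199 * 128
    spec = eb.SynthSpec(
        n_channels=1, fs=FS, duration=n / FS, background_slope=0.0,
        background_rms=0.5, qpc_triplets=[(6.0, 9.0, 0.0, 1.0)], seed=11,
    )
    rec = eb.build_recording(spec)
    return eb.make_epochs(rec), rec


@pytest.fixture(scope="session")
def sinusoid_epochs():
    """60 s of 10 Hz unit sinusoid, single channel, default epoching."""
    t = np.arange(int(60 * FS)) / FS
    rec = eb.Recording(data=np.cos(2 * np.pi * 10 * t)[None, :], fs=FS,
                       labels=["A"])
    return eb.make_epochs(rec)


@pytest.fixture(scope="session")
def incision_ea_result():
    """Full pipeline run on the synthetic incision/EA study (shared: this
    is the most expensive fixture in the suite)."""
    return eb.run_incision_ea_study(n_rats=8, duration=60.0, seed=42)
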