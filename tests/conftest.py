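import numpy as np
import pytest

from retinaphys import core_io, synthetic
from retinaphys.datasets import load_rgc_profiles


@pytest.fixture(scope="session")
def rgc_profiles():
    """Packaged per-cell intrinsic-property table (bovine n=10, mouse n=9)."""
    return load_rgc_profiles()


@pytest.fixture
def small_recording():
    rng = np.random.default_rng(0)
    return core_io.Recording(
        samples=rng.normal(0, 5, size=(3, 2500)), rate=25000.0,
        channels=("e1", "e2", "e3"),
    )


@pytest.fixture(scope="session")
def trial_epochs():
    """Ten identical 1-s light steps, 4 s apart, protocol contrast ~0.89."""
    return [
        core_io.StimulusEpoch(onset=2.0 + 4.0 * k, duration=1.0,
                              flux=8.5e14, background=5e13)
        for k in range(10)
    ]


def bleach_protocol(model: synthetic.MERGModel):
    """Dark test flash, bleaching flash, 15-s post-bleach test, 5-min recovery test."""
    test = dict(duration=1.0, flux=3.2e15, background=0.0)
    return [
        core_io.StimulusEpoch(onset=5.0, **test),
        core_io.StimulusEpoch(onset=10.0, duration=2.0,
                              flux=model.bleach_flux * 10, background=0.0),
        core_io.StimulusEpoch(onset=27.0, **test),
        core_io.StimulusEpoch(onset=312.0, **test),
    ]


@pytest.fixture(scope="session")
def clamp_currents():
    return [-100.0, -50.0, -25.0, 50.0, 100.0, 200.0]
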