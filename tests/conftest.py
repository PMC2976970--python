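import pytest

from notchscreen import ScreenModel
from notchscreen import simulate as sim


@pytest.fixture(scope="session")
def null_screen():
    """A no-spike screen: 4 stock plates x 96 dsRNAs, duplicates."""
    cfg = sim.SimulationConfig(seed=11)
    pm, meas, ann = sim.generate_screen(cfg)
    return cfg, pm, meas, ann


@pytest.fixture(scope="session")
def null_result(null_screen):
    _, pm, meas, ann = null_screen
    return ScreenModel(meas, pm, ann).fit()


@pytest.fixture(scope="session")
def controls_result():
    """A fitted screen carrying the canonical spiked controls."""
    cfg = sim.spike_canonical_controls(sim.SimulationConfig(seed=3))
    pm, meas, ann = sim.generate_screen(cfg)
    return ScreenModel(meas, pm, ann).fit()
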