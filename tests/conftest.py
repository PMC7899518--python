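import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pulsegate.chain import BackgroundModel, DetectionChain, TimingConfig
from pulsegate.experiment import ExperimentConfig
from pulsegate.phantom import Bead, BeadPhantom
from pulsegate.scan import ScanConfig

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def timing():
    return TimingConfig()


@pytest.fixture(scope="session")
def tiny_scan():
    """60 lines x 80 px, 0.1 ms lines: 5820 oversampled / 100 slow samples
    per line."""
    return ScanConfig.reduced(n_lines=60, n_pixels_x=80, line_period_ms=0.2)


@pytest.fixture(scope="session")
def tiny_cfg(tiny_scan):
    """Fast four-frame experiment; chopper sped up to 250 Hz so a 6 ms frame
    still contains full open and closed stripes."""
    return ExperimentConfig(
        scan=tiny_scan,
        background=BackgroundModel(waveform="chopped", amplitude=3.0,
                                   chop_rate_hz=250.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_run(tiny_cfg):
    from pulsegate.experiment import run_experiment

    return run_experiment(tiny_cfg)


@pytest.fixture(scope="session")
def noisefree_chains():
    return (DetectionChain.mode1(shot_noise_scale=0.0, dark_noise_sigma=0.0),
            DetectionChain.mode2(shot_noise_scale=0.0, dark_noise_sigma=0.0))


@pytest.fixture
def flat_phantom():
    """Uniform yield 1 everywhere (one disk larger than the FOV)."""
    return BeadPhantom(fov_um=300.0, beads=[Bead(150.0, 150.0, 1e4, 1.0)])
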