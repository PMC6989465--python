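import numpy as np
import pytest

from gma.config import PipelineConfig
from gma.pipeline import analyze
from gma.synthetic import LimbSpec, MotionScenario, generate_video


@pytest.fixture(scope="session")
def limb_video():
    """Desk-scale recording: one lower-left limb stroking at 1.5 Hz."""
    scenario = MotionScenario(
        frame_size=(240, 320),
        body_axes=(150.0, 75.0),
        n_frames=900,
        limbs=[LimbSpec("LL", 1.5, 20.0)],
        noise_sd=2.0,
        seed=1,
    )
    return generate_video(scenario)


@pytest.fixture(scope="session")
def limb_config():
    return PipelineConfig(threshold=60.0, background=60.0)


@pytest.fixture(scope="session")
def limb_analysis(limb_video, limb_config):
    seq, _ = limb_video
    return analyze(seq, limb_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
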