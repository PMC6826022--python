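import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fishheart import synthetic as syn
from fishheart.video import AnalysisConfig, summarize_heart

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_video():
    """Default noiseless beating-heart video (EDV=4, ESV=2 mm^3, 2 Hz, 66 fps)."""
    return syn.gen_beating_heart_video(syn.CardiacSimParams(noise_sd=0.0, seed=0))


@pytest.fixture(scope="session")
def noiseless_summary(noiseless_video):
    video, _ = noiseless_video
    return summarize_heart(video, AnalysisConfig(pacing_rate=2.0))


@pytest.fixture(scope="session")
def clean_masks_video():
    """Noiseless, unblurred video whose frames are exact ellipse silhouettes."""
    return syn.gen_beating_heart_video(
        syn.CardiacSimParams(noise_sd=0.0, blur_sigma=0.0, seed=0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
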