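import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gaitfuse as gf
from gaitfuse.synthetic_gait import GaitScheduleConfig, generate_recording

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_recording():
    """5-cycle synthetic recording with its generating schedule."""
    rec, truth = generate_recording(GaitScheduleConfig(n_cycles=5), seed=0)
    return rec, truth


@pytest.fixture(scope="session")
def small_dataset(small_recording):
    """Feature dataset built end-to-end from the 5-cycle recording."""
    rec, truth = small_recording
    filtered = gf.denoise_semg(rec.semg)
    labels = gf.label_recording(rec)
    assert np.array_equal(labels, truth)  # noiseless-threshold recovery
    return gf.build_dataset(filtered, rec.angle, labels)
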