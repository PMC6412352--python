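import numpy as np
import pytest

from steerwake.preprocess import WindowSegment
from steerwake.simdata import ScenarioConfig, generate_feature_bench, generate_trace


@pytest.fixture(scope="session")
def short_trace():
    """A 2-minute drive covering awake, transition and drowsy phases."""
    return generate_trace(ScenarioConfig(duration_s=120.0, seed=42))


@pytest.fixture(scope="session")
def bench():
    """Planted bench at study conditions: 36 features, 5 informative, d=2."""
    X, y, informative = generate_feature_bench(
        n_samples=2000, n_features=36, n_informative=5, effect_size=2.0, seed=123
    )
    return X, y, informative


def make_segment(angle, velocity=None, label=0):
    """Build a detrended WindowSegment from raw arrays (test helper)."""
    angle = np.asarray(angle, float)
    velocity = (
        np.asarray(velocity, float) if velocity is not None else np.gradient(angle)
    )
    return WindowSegment(
        index=0,
        start_sample=0,
        angle_detrended=angle - angle.mean(),
        velocity_detrended=velocity - velocity.mean(),
        label=label,
    )
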