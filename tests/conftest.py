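import numpy as np
import pytest

from pulsecam import (
    FixtureBoxDetector,
    StreamSpec,
    SyntheticSpec,
    open_source,
    run_pipeline,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_spec():
    """The study conditions: 12 s @ 30 fps, 640x360, 1.2 Hz cardiac /
    0.25 Hz respiratory, green amplitude 2, unit pixel noise, seed 7."""
    return SyntheticSpec()


@pytest.fixture
def small_spec():
    """A fast low-resolution clip for unit tests that only need a valid
    stream, not the full study geometry."""
    return SyntheticSpec(
        resolution=(160, 120),
        face_box=(40, 20, 80, 80),
        duration_s=2.0,
        noise_sigma=0.5,
    )


@pytest.fixture(scope="session")
def default_rppg_run():
    """One shared rPPG pipeline pass over the default synthetic clip."""
    spec = SyntheticSpec()
    stream = open_source(StreamSpec(source=spec, nominal_fps=spec.fps))
    return run_pipeline(stream, method="rppg", detector=FixtureBoxDetector(spec))
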