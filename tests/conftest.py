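import numpy as np
import pytest

from flymotion import stimuli


@pytest.fixture
def uniform_movie():
    """Small static uniform movie at mean luminance 0.5."""
    lum = np.full((40, 40, 60), 0.5, dtype=np.float32)
    return stimuli.StimulusMovie(lum)


@pytest.fixture
def small_grating():
    """Full-size spatial grid, short 1 Hz preferred-direction grating."""
    return stimuli.make_grating(
        stimuli.GratingSpec(temporal_frequency=1.0), dims=(200, 200, 300)
    )
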