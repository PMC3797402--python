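import numpy as np
import pytest

from nirsfuse.io import StimulusParadigm, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def paradigm():
    """The finger-tapping block design: 42 s first onset, 21 s task / 30 s rest x 10."""
    return StimulusParadigm(42.0, 21.0, 30.0, 10)


@pytest.fixture
def epoch_time_axis():
    """684-sample epoch axis, -35 s ... +35 s at 9.75 Hz."""
    return np.arange(684) / 9.75 - 35.0


@pytest.fixture
def small_grid():
    return VolumeGrid(shape=(8, 8, 4), affine=np.eye(4), mask=np.ones((8, 8, 4), bool))
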