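import numpy as np
import pytest

from hybridnav.carm import CArmModel


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def parallel_model():
    """Parallel-projection C-arm with a centered principal point."""
    return CArmModel(px_per_mm=2.0, principal_point_px=np.array([128.0, 128.0]))


@pytest.fixture
def pinhole_model():
    return CArmModel(
        px_per_mm=2.0,
        principal_point_px=np.array([128.0, 128.0]),
        projection_mode="pinhole",
        source_detector_distance_mm=1000.0,
    )
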