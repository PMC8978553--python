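import numpy as np
import pytest

from msdrift.localization_io import LocalizationTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table_2d():
    """Three localizations over two frames, 2D, with precision."""
    return LocalizationTable(
        frame=np.array([1, 1, 2]),
        xy=np.array([[0.0, 0.0], [100.0, 0.0], [25.0, 25.0]]),
        precision=np.array([10.0, 10.0, 12.0]),
    )


@pytest.fixture
def small_table_3d():
    return LocalizationTable(
        frame=np.array([1, 2, 3]),
        xy=np.array([[0.0, 0.0, 5.0], [100.0, 0.0, -5.0], [25.0, 25.0, 0.0]]),
    )
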