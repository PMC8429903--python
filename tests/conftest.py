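import numpy as np
import pytest

from tpmratio import AcquisitionParams, TwoChannelStack


@pytest.fixture
def small_acquisition() -> AcquisitionParams:
    """A 16x16x5 acquisition spanning the default 80-200 um window."""
    return AcquisitionParams(
        image_size=16,
        pixel_size_um=4.0,
        z_positions_um=tuple(np.linspace(80.0, 200.0, 5)),
    )


def make_stack(ch1, ch2, z=None, **kwargs) -> TwoChannelStack:
    """Build a stack from plain nested lists/arrays, broadcasting to 3-D."""
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if ch1.ndim == 2:
        ch1, ch2 = ch1[None], ch2[None]
    if z is None:
        z = np.arange(ch1.shape[0], dtype=float) * 10.0 + 80.0
    return TwoChannelStack(ch1=ch1, ch2=ch2, z_positions_um=z,
                           pixel_size_um=1.0, **kwargs)


@pytest.fixture
def uniform_stack() -> TwoChannelStack:
    """3 sections of 4x4, constant ratio 2.0, bright enough to mask fully."""
    ch1 = np.full((3, 4, 4), 100.0)
    ch2 = np.full((3, 4, 4), 200.0)
    return make_stack(ch1, ch2, z=np.array([80.0, 140.0, 200.0]))
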