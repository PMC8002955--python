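import numpy as np
import pytest

from hemoflow.io import ImageStack


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def random_stack_factory(rng):
    """Build small random stacks: random_stack(n_frames, h, w, bit_depth)."""

    def make(n_frames=5, h=8, w=8, bit_depth=8, **kwargs):
        if bit_depth == 8:
            data = rng.integers(0, 256, size=(n_frames, h, w), dtype=np.uint8)
        else:
            data = rng.integers(0, 65536, size=(n_frames, h, w), dtype=np.uint16)
        return ImageStack(data, **kwargs)

    return make
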