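import numpy as np
import pytest

from slfcn.softlabel import InstanceAnnotation


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def block_instance(x0, y0, side_x, side_y, class_label="nucleus", instance_id=1):
    """Solid rectangular instance with corner (x0, y0)."""
    pixels = frozenset((x, y) for x in range(x0, x0 + side_x)
                       for y in range(y0, y0 + side_y))
    return InstanceAnnotation(pixels, class_label, instance_id)


@pytest.fixture
def square_80_in_128():
    """The 80x80 solid-square annotation centred in a 128x128 image."""
    return block_instance(20, 20, 80, 80), (128, 128)
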