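import numpy as np
import pytest

from scopeqc.core import ImageStack


def make_stack(pixels, **kwargs):
    """Wrap an array (promoted to 5-D t,c,z,y,x) in an ImageStack."""
    pixels = np.asarray(pixels)
    while pixels.ndim < 5:
        pixels = pixels[None]
    kwargs.setdefault("channel_wavelengths", [488.0] * pixels.shape[1])
    return ImageStack(pixels=pixels, **kwargs)


@pytest.fixture
def simple_config_text():
    return (
        "# demo\n"
        "system=TestScope\n"
        "objectives=10x,20x,63x\n"
        "lasers.field=405,488,561,633\n"
    )
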