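import numpy as np
import pytest

from skincal.synthetic import SceneSpec, render_chart


@pytest.fixture(scope="session")
def ideal_scene():
    """Default 4x4 skin-tone chart rendered without distortion."""
    spec = SceneSpec()
    image, layout, reference = render_chart(spec)
    return spec, image, layout, reference


@pytest.fixture()
def rng():
    return np.random.default_rng(20210213)
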