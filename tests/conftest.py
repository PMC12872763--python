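import math

import numpy as np
import pytest

from stipemorph.synthetic import make_curved_band, make_rectangle, render


@pytest.fixture(scope="session")
def rect_fixture():
    """Straight 401x101 band with its analytic truth."""
    return make_rectangle(401, 101)


@pytest.fixture(scope="session")
def band_fixture():
    """Curved band R=300, t=50, theta=pi/3 with its analytic truth."""
    return make_curved_band(300, 50, math.pi / 3)


@pytest.fixture(scope="session")
def rect_image(rect_fixture):
    mask, _ = rect_fixture
    return render(mask, fg_color=(107, 100, 87), background="green")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
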