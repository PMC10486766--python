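import numpy as np
import pytest

from riceq import CurveSpec, ImageSpec, PanelSpec, make_curve, make_image, make_panel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_image():
    """A 64×48 synthetic frame with a known yellow count, no noise."""
    spec = ImageSpec(width=64, height=48, n_grains=40, yellow_fraction=0.3,
                     noise_sd=0.0, seed=11)
    return make_image(spec)


@pytest.fixture
def default_curve():
    """Noiseless two-cycle curve with closed-form feature truth."""
    return make_curve(CurveSpec(seed=5))


@pytest.fixture
def small_panel():
    """Balanced 40-variety × 2-year panel, replicate-averaged truth exact."""
    spec = PanelSpec(n_varieties=40, n_reps=1, noise_sd=0.0, seed=21)
    return make_panel(spec)
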