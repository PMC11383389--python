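import numpy as np
import pytest

from chorangio.phantom import PhantomParams, generate_sample


def small_params(**overrides) -> PhantomParams:
    base = dict(
        image_height=48,
        image_width=64,
        rpe_depth=10,
        cc_thickness=2,
        sl_thickness=12,
        hl_thickness=18,
        sv_radius_range=(1.0, 2.0),
        hv_radius_range=(2.5, 4.5),
        surface_wave_amplitude=1.5,
        seed=0,
    )
    base.update(overrides)
    return PhantomParams(**base)


@pytest.fixture
def params():
    return small_params()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def hd_sample(params, rng):
    return generate_sample(params, rng, "hd")
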