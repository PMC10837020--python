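import numpy as np
import pytest

from photothermal.aci import CI_SEQUENCE, AciCurve
from photothermal.fvcb import PhotoCapacity, net_assimilation
from photothermal.kinetics import celsius_to_kelvin, load_default_config, to_partial_pressure


@pytest.fixture(scope="session")
def kcfg():
    return load_default_config()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_curve(kcfg, cap: PhotoCapacity, t_leaf_c=25.0, pressure=96.0, noise_sd=0.0,
               rng=None, **meta):
    """Forward-generate one A-Ci curve at the standard 13-step sequence."""
    ci = np.array(CI_SEQUENCE, dtype=float)
    ci_pa = to_partial_pressure(ci, pressure)
    t_k = celsius_to_kelvin(t_leaf_c)
    an = np.array([net_assimilation(float(c), t_k, kcfg, cap)[0] for c in ci_pa])
    if noise_sd > 0:
        an = an + rng.normal(0.0, noise_sd, size=an.size)
    return AciCurve(ci=ci, an=an, t_leaf=t_leaf_c, irradiance=1500.0,
                    pressure=pressure, **meta)


@pytest.fixture
def forward_curve():
    return make_curve
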