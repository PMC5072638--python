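import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from macusym import Eye, Layer, ThicknessGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20160)


def random_grid(rng, shape=(31, 31), layer=Layer.GCIPL, laterality=Eye.OD,
                missing_frac=0.0, lo=40.0, hi=120.0):
    values = rng.uniform(lo, hi, size=shape)
    if missing_frac > 0:
        mask = rng.random(shape) < missing_frac
        values[mask] = np.nan
    return ThicknessGrid(values=values, layer=layer, laterality=laterality)


@pytest.fixture
def make_grid(rng):
    def _make(**kw):
        return random_grid(rng, **kw)

    return _make
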