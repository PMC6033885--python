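import numpy as np
import pytest

import borerisk as br
from borerisk.grid import EnvStack, GridGeoref


@pytest.fixture(scope="session")
def small_landscape():
    """A 40x40 two-layer autocorrelated landscape with known suitability."""
    spec = br.LandscapeSpec(shape=(40, 40), n_layers=2, correlation_length=5.0,
                            seed=7)
    stack = br.gen_env_stack(spec)
    suit = br.gen_true_suitability(stack, (2.0, -1.0))
    return stack, suit


@pytest.fixture(scope="session")
def trained_model(small_landscape):
    stack, suit = small_landscape
    occs = br.sample_occurrences(suit, 300, seed=11)
    model = br.fit_gibbs(occs, stack)
    return stack, suit, occs, model


def make_stack(values_by_layer: dict, cell: float = 0.5, x_min: float = -100.0,
               y_max: float = 30.0, mask=None) -> EnvStack:
    """Small helper to build a stack from explicit per-layer arrays."""
    names = list(values_by_layer)
    arrs = np.stack([np.asarray(values_by_layer[n], float) for n in names])
    if mask is None:
        mask = ~np.isfinite(arrs).all(axis=0)
    georef = GridGeoref(x_min=x_min, y_max=y_max, cell=cell)
    return EnvStack(names, arrs, mask, georef)
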