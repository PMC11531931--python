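import numpy as np
import pytest

from deerlcu.landcover import HabitatGrid, HabitatGroup


def make_habitat(groups, cell_size_m=30.0, origin=None, year_label=2021):
    """Build a HabitatGrid from a nested list / array of group codes."""
    groups = np.asarray(groups, dtype=np.int8)
    if origin is None:
        origin = (0.0, groups.shape[0] * cell_size_m)
    return HabitatGrid(
        groups=groups, cell_size_m=cell_size_m, origin=origin, year_label=year_label
    )


def random_habitat(rng, shape=(50, 50), p_sf=0.3, p_food=0.3, cell_size_m=30.0):
    groups = rng.choice(
        [
            HabitatGroup.NONE.value,
            HabitatGroup.SHELTER_FOOD.value,
            HabitatGroup.FOOD.value,
        ],
        size=shape,
        p=[1 - p_sf - p_food, p_sf, p_food],
    ).astype(np.int8)
    return make_habitat(groups, cell_size_m=cell_size_m)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def small_fit():
    """One shared small-panel HMC fit (module tests reuse it to stay fast)."""
    from deerlcu.synthetic import PanelParams, simulate_density_panel
    from deerlcu.validation import GammaGLMMConfig, fit_gamma_multilevel

    params = PanelParams(n_units=120, n_years=6, seed=3)
    panel = simulate_density_panel(None, params)
    config = GammaGLMMConfig(chains=4, warmup=700, draws=700, seed=11)
    result = fit_gamma_multilevel(panel, config)
    return params, panel, result
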