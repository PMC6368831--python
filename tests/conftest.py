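import numpy as np
import pytest

from nichekit.grids import EnvStack, Grid
from nichekit.simulate import (
    VirtualSpeciesConfig,
    generate_env,
    sample_occurrences,
    true_suitability,
)

IDENTITY_TRANSFORM = (0.0, 1.0, 0.0, 0.0, 0.0, -1.0)


def make_grid(values, mask=None, transform=IDENTITY_TRANSFORM):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros_like(values, dtype=bool)
    return Grid(values=values, nodata_mask=np.asarray(mask, bool), transform=transform)


def make_stack(arrays, names=None, transform=IDENTITY_TRANSFORM):
    grids = [make_grid(a, transform=transform) for a in arrays]
    names = names or [f"env_{i + 1}" for i in range(len(grids))]
    return EnvStack(layers=grids, names=names)


@pytest.fixture(scope="session")
def species_cfg():
    return VirtualSpeciesConfig(seed=42)


@pytest.fixture(scope="session")
def default_species(species_cfg):
    """The default virtual species: (config, env stack, truth, occurrences)."""
    stack = generate_env(species_cfg)
    suit = true_suitability(stack, species_cfg)
    occs = sample_occurrences(suit, species_cfg)
    return species_cfg, stack, suit, occs


@pytest.fixture(scope="session")
def sim_project(tmp_path_factory, species_cfg):
    """A simulated on-disk project layout shared by pipeline tests."""
    from nichekit.simulate import simulate_project

    root = tmp_path_factory.mktemp("vsp_project")
    layout, stack, suit, occs = simulate_project(root, species_cfg)
    return layout, stack, suit, occs
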