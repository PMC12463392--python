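import numpy as np
import pytest

from l1quant.atlas import RegionHierarchy
from l1quant.synthdata import (
    CellPopulationSpec,
    RegionSpec,
    generate_brain_image,
    generate_region_map,
)

TARGET_FRACTIONS = (0.10, 0.17, 0.24, 0.31)


def make_brain(
    shape=(512, 512),
    density=300.0,
    target_fractions=TARGET_FRACTIONS,
    age_effect=1.0,
    seed=0,
    pixel_size=1.0,
):
    """Four-subregion synthetic brain with programmed target fractions.

    The target-positive fraction is made independent of neuronal identity so
    the programmed per-subregion fraction equals the overall one.
    """
    specs = [
        RegionSpec(i + 1, "cortex" if i < 2 else "midbrain", 0.25,
                   background_mean=100.0 + 40.0 * i, background_sd=8.0)
        for i in range(len(target_fractions))
    ]
    region_map, hier_table = generate_region_map(specs, shape, pixel_size, seed=seed)
    populations = {
        i + 1: CellPopulationSpec(
            density=density,
            neuron_fraction=0.4,
            target_pos_fraction_in_neurons=f,
            target_pos_fraction_in_nonneurons=f,
            age_effect=age_effect,
        )
        for i, f in enumerate(target_fractions)
    }
    region_specs = {s.subregion_id: s for s in specs}
    bundle, truth = generate_brain_image(
        region_map, populations, region_specs, pixel_size, "2D", seed=seed
    )
    hierarchy = RegionHierarchy.from_table(hier_table, pixel_size=pixel_size)
    return region_map, hierarchy, bundle, truth


@pytest.fixture(scope="session")
def small_brain():
    return make_brain(shape=(512, 512), seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
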