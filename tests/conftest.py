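import numpy as np
import pytest

from canopycomplete.datagen import DatasetConfig
from canopycomplete.plants import DEFAULT_ARCHETYPES, PlantArchetype, generate_plant
from canopycomplete.scene import PlotLayout, assemble_population


def tiny_archetype(stage: str, n_points: int = 80) -> PlantArchetype:
    """Down-pointed clone of a default archetype for fast tests."""
    from dataclasses import replace
    return replace(DEFAULT_ARCHETYPES[stage], n_surface_points=n_points)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def bolting_pool():
    arch = tiny_archetype("bolting")
    return [generate_plant(arch, s) for s in range(3)]


@pytest.fixture(scope="session")
def tiny_scene(bolting_pool):
    layout = PlotLayout(rows=2, cols=2)
    return assemble_population(bolting_pool, layout, seed=0)


@pytest.fixture(scope="session")
def tiny_dataset_config():
    return DatasetConfig(
        stages=("bolting",),
        n_scenes_per_stage=2,
        pool_size=4,
        layout=PlotLayout(rows=2, cols=2),
        rig_azimuth_step_deg=30.0,
        n_blocks=1,
        block_size=128,
        archetypes={"bolting": tiny_archetype("bolting")},
    )
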