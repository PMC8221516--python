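"""Shared fixtures: packaged parameters, effects curves, a synthetic
landscape, and the three 50-year scenario runs used by several tests.

Everything is generated programmatically and seeded; the expensive
session-scoped fixtures are built once.
"""

import numpy as np
import pytest

from avirisk.config import packaged_chemical, packaged_species
from avirisk.demography import VitalRates
from avirisk.effects import build_effects_curve
from avirisk.engine import ScenarioConfig, run_scenario
from avirisk.landscape import aggregate_patches, build_hex_grid, rasterize_to_hexagons
from avirisk.synth import SyntheticLandscapeSpec, generate_crop_map, generate_habitat_map

LANDSCAPE_SEED = 42
SCENARIO_SEED = 7


@pytest.fixture(scope="session")
def species():
    return packaged_species()


@pytest.fixture(scope="session")
def table_vitals():
    """Best-habitat gnatcatcher vital rates."""
    return VitalRates(s_j=0.4314, s_a=0.52, f=2.26)


@pytest.fixture(scope="session")
def repro_chem():
    return packaged_chemical("reproductive_stressor")


@pytest.fixture(scope="session")
def surv_chem():
    return packaged_chemical("survival_stressor")


@pytest.fixture(scope="session")
def repro_curves(species, repro_chem):
    return {
        k: build_effects_curve(repro_chem, k, species.breeding, species.forager)
        for k in (2, 3, 4)
    }


@pytest.fixture(scope="session")
def surv_curves(species, surv_chem):
    return {
        k: build_effects_curve(surv_chem, k, species.breeding, species.forager)
        for k in (2, 3, 4)
    }


def make_patches(extent_km=8.0, resolution_m=60.0, seed=LANDSCAPE_SEED):
    spec = SyntheticLandscapeSpec(extent_km=extent_km, resolution_m=resolution_m)
    rng = np.random.default_rng(seed)
    habitat = generate_habitat_map(spec, rng)
    crop = generate_crop_map(spec, habitat, rng)
    grid = build_hex_grid((extent_km * 1000.0, extent_km * 1000.0))
    return aggregate_patches(
        grid, rasterize_to_hexagons(habitat, grid), rasterize_to_hexagons(crop, grid)
    )


@pytest.fixture(scope="session")
def synthetic_patches():
    return make_patches()


@pytest.fixture(scope="session")
def scenario_runs(species, synthetic_patches, repro_curves, surv_curves):
    """50-year trajectories for control and both stressors (shared seed)."""
    out = {}
    for name, curves in (
        ("control", None),
        ("reproductive_stressor", repro_curves),
        ("survival_stressor", surv_curves),
    ):
        config = ScenarioConfig(
            years=50,
            n_realization_maps=50,
            n_trials=4,
            n_replicates=25,
            seed=SCENARIO_SEED,
            chemical=name,
        )
        out[name] = run_scenario(
            synthetic_patches, species.vitals, species.coeffs, config, curves=curves
        )
    return out
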