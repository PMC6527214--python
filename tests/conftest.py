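"""Shared fixtures: reference ANOVA inputs and a small synthetic study."""

import numpy as np
import pytest

from cafeqg.anova import Factor, ModelSpec
from cafeqg.synthetic import SimulationConfig, simulate_study

# Externally tabulated four-way mixed-model ANOVA mean squares for a
# 46-line, 3-exposure, 2-solution, 2-sex, 10-vial two-choice consumption
# experiment (two drug treatments, A and B).  Used as frozen inputs to
# verify that the EMS machinery reproduces the known F ratios, variance
# components and standard errors of that analysis.
REFERENCE_MS_A = {
    "L": 9822.0, "E": 12579.0, "S": 15088.0, "X": 223732.0,
    "L×E": 846.8, "L×S": 930.9, "E×S": 812.9, "L×X": 1317.0,
    "E×X": 3530.0, "S×X": 955.5, "L×E×S": 533.0, "L×E×X": 275.1,
    "L×S×X": 396.7, "E×S×X": 917.1, "L×E×S×X": 269.8, "residual": 267.3,
}
REFERENCE_MS_B = {
    "L": 7426.77, "E": 21687.0, "S": 31338.0, "X": 179509.0,
    "L×E": 1251.40, "L×S": 840.12, "E×S": 208.98, "L×X": 1106.92,
    "E×X": 3333.61, "S×X": 806.85, "L×E×S": 448.30, "L×E×X": 298.62,
    "L×S×X": 384.45, "E×S×X": 880.99, "L×E×S×X": 206.94, "residual": 234.92,
}

# the matching published variance-component columns (sigma^2 per random term)
REFERENCE_SIGMA2_A = {
    "L": 63.86, "L×E": 7.71, "L×S": 4.52, "L×X": 15.24, "L×E×S": 13.16,
    "L×E×X": 0.27, "L×S×X": 4.23, "L×E×S×X": 0.25, "residual": 267.28,
}
REFERENCE_SIGMA2_B = {
    "L": 42.71, "L×E": 18.48, "L×S": 4.03, "L×X": 10.98, "L×E×S": 10.69,
    "L×E×X": 3.20, "L×S×X": 5.00, "L×E×S×X": 0.0, "residual": 243.42,
}


@pytest.fixture(scope="session")
def panel_model() -> ModelSpec:
    """46 random lines x 3 exposures x 2 solutions x 2 sexes, 10 vials."""
    return ModelSpec(
        factors=(
            Factor("L", 46, fixed=False),
            Factor("E", 3, fixed=True),
            Factor("S", 2, fixed=True),
            Factor("X", 2, fixed=True),
        ),
        n_replicates=10,
    )


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down but structurally complete study."""
    return SimulationConfig(
        seed=11, n_lines=12, n_vials=4, n_variants=200, n_genes=80,
        planted_module_size=6, n_causal=3, background_edge_prob=0.01,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
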