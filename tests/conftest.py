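"""Shared fixtures: a small simulated cohort with first-level fits.

The session-scoped cohort keeps the expensive BOLD simulation + GLM work
out of individual tests; anything mutating records must copy first.
"""

from __future__ import annotations

import numpy as np
import pytest

import compfmri as cf
from compfmri.glm import build_design, fit_prewhitened_glm, grand_mean_scale


@pytest.fixture(scope="session")
def small_cohort():
    """Ten participants, an MDN-like region plus a pattern-carrying
    candidate region, on a small grid."""
    specs = [
        cf.RegionSpec(label="mdn", n_voxels=32, base_contrast=0.8),
        cf.RegionSpec(
            label="comp", n_voxels=32, base_contrast=0.0,
            unique_info_base=0.5,
        ),
    ]
    config = cf.SimulationConfig(
        n_participants=10, grid_shape=(12, 8, 8), region_specs=specs, seed=101
    )
    return cf.simulate_cohort(config)


@pytest.fixture(scope="session")
def fitted_participant(small_cohort):
    """(scaled dataset, design matrix, GLM result, truth) for one subject."""
    rec = small_cohort.records[4]
    dataset, truth = small_cohort.bold_for(rec)
    scaled, _ = grand_mean_scale(dataset)
    design = build_design(small_cohort.design)
    glm_result = fit_prewhitened_glm(scaled, design)
    return scaled, design, glm_result, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
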