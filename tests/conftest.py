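"""Shared fixtures.

The heavy session fixtures (optimized plan, offset-coupling study) are
computed once and reused across test modules; their problem sizes are the
package's standard desk-scale study conditions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from lungsbrt import (
    ExperimentConfig,
    PhantomSpec,
    build_phantom,
    generate_beamset,
    optimize_weights,
    run_offset_coupling,
)
from lungsbrt.epl import BeamDoseModel
from lungsbrt.grids import DensityGrid
from lungsbrt.mc import McConfig


@pytest.fixture(scope="session")
def model() -> BeamDoseModel:
    return BeamDoseModel()


@pytest.fixture(scope="session")
def fast_mc() -> McConfig:
    """Reduced-statistics transport settings for unit-level checks."""
    return McConfig(seed=7, initial_histories=300_000, histories_cap=300_000,
                    uncertainty_target=0.5)


@pytest.fixture(scope="session")
def water_grid() -> DensityGrid:
    shape = (40, 40, 48)
    spacing = (2.5, 2.5, 2.5)
    origin = tuple(-(np.asarray(shape) - 1) / 2.0 * np.asarray(spacing))
    return DensityGrid(np.ones(shape, dtype=np.float32), spacing, origin)


@pytest.fixture(scope="session")
def phantom():
    """Standard study phantom (20 cc GTV, 3 mm margin), one fixed seed."""
    return build_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def optimized_plan(phantom, model):
    grid, structures = phantom
    center = (
        np.asarray(structures.spacing) * np.argwhere(structures["GTV"]).mean(axis=0)
        + np.asarray(structures.origin)
    )
    beams = generate_beamset(100, center, (20.0, 25.0, 30.0, 35.0, 40.0), seed=1)
    return optimize_weights(grid, structures, beams, model=model)


@pytest.fixture(scope="session")
def coupling_study():
    """The offset-coupling measurement at the standard study conditions:
    three replicate phantoms, +/-3 mm craniocaudal offsets, both engines."""
    cfg = ExperimentConfig(replicate_seeds=(0, 1, 2))
    return run_offset_coupling(cfg, offsets_mm=(-3.0, 3.0), include_mc=True)
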