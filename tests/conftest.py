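"""Shared fixtures: tiny analytic grids and seeded synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from vimloc.core import VoxelGrid
from vimloc.crf import TrainingConfig
from vimloc.simulate import CohortSpec, DegradationSpec, generate_cohort
from vimloc.workflow import run_study


def make_line_grid(n: int, spacing: float = 1.0) -> VoxelGrid:
    """n voxels along one axis — the smallest grid with nontrivial adjacency."""
    affine = np.diag([spacing, spacing, spacing, 1.0])
    idx = np.array([[i, 0, 0] for i in range(n)])
    return VoxelGrid((n, 1, 1), (spacing,) * 3, affine, idx)


def make_box_grid(shape=(4, 4, 4), spacing: float = 1.0) -> VoxelGrid:
    affine = np.diag([spacing, spacing, spacing, 1.0])
    idx = np.argwhere(np.ones(shape, dtype=bool))
    return VoxelGrid(shape, (spacing,) * 3, affine, idx)


@pytest.fixture(scope="session")
def small_cohort():
    """Eight subjects, default study conditions, fixed seed."""
    return generate_cohort(CohortSpec(n_subjects=8, seed=3))


@pytest.fixture(scope="session")
def study_result():
    """The scaled-down headline experiment: 40 train / 20 test subjects,
    low-angular degradation with 0.3 tract-dropout probability, models
    trained on both feature qualities."""
    spec = CohortSpec(
        n_subjects=60,
        seed=11,
        degradation=DegradationSpec(mode="low_angular", dropout_prob=0.3),
    )
    subjects = generate_cohort(spec)
    return run_study(
        subjects[:40],
        subjects[40:],
        TrainingConfig(seed=0),
        with_hq_model=True,
    )
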