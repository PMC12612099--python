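"""Connectivity-driven Vim baseline.

The classical tractography recipe: threshold the M1 tract-density map at its
upper 40%, multiply by the contralateral-cerebellum map thresholded at its
lower 30%, and binarise the product at a lower 30% threshold.  The cuts
exclude spurious connections and keep only voxels with robust connectivity
to both targets; the surviving voxels are the connectivity-driven Vim.

Percentiles are computed over the nonzero mask voxels by default (tract
densities are mostly zero away from the tract, and including the zeros
would make the cuts vacuous); ties at the cut are retained.  An empty
result is a valid outcome, not an error — with degraded angular resolution
the tractography-derived maps often fail to produce any surviving cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import LabelField, VoxelGrid

Population = Literal["nonzero_mask_voxels", "all_mask_voxels"]

__all__ = [
    "ThresholdSpec",
    "threshold_upper",
    "threshold_lower",
    "connectivity_driven_vim",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """Percentile cuts of the connectivity-driven recipe."""

    m1_upper_pct: float = 40.0
    cereb_lower_pct: float = 30.0
    product_lower_pct: float = 30.0
    percentile_population: Population = "nonzero_mask_voxels"

    def __post_init__(self) -> None:
        for p in (self.m1_upper_pct, self.cereb_lower_pct, self.product_lower_pct):
            if not 0 < p < 100:
                raise ValueError(f"percentages must be in (0, 100), got {p}")


def _population(field: np.ndarray, population: Population) -> np.ndarray:
    if population == "all_mask_voxels":
        return field
    if population == "nonzero_mask_voxels":
        return field[field > 0]
    raise ValueError(f"unknown percentile population {population!r}")


def threshold_upper(
    field: np.ndarray, pct: float, population: Population = "nonzero_mask_voxels"
) -> np.ndarray:
    """Keep the upper ``pct`` percent of values; zero the rest.

    Voxels at or above the (100 - pct)-th percentile of the population
    retain their value (ties kept); percentile uses linear interpolation.
    """
    field = np.asarray(field, dtype=float)
    pop = _population(field, population)
    if pop.size == 0:
        raise ValueError("empty percentile population")
    cut = np.percentile(pop, 100.0 - pct)
    out = np.where(field >= cut, field, 0.0)
    return out


def threshold_lower(
    field: np.ndarray, pct: float, population: Population = "nonzero_mask_voxels"
) -> np.ndarray:
    """Discard the lowest ``pct`` percent of values; keep the rest.

    Voxels at or above the ``pct``-th percentile of the population retain
    their value (ties kept).
    """
    field = np.asarray(field, dtype=float)
    pop = _population(field, population)
    if pop.size == 0:
        raise ValueError("empty percentile population")
    cut = np.percentile(pop, pct)
    return np.where(field >= cut, field, 0.0)


def connectivity_driven_vim(
    grid: VoxelGrid,
    m1_map: np.ndarray,
    cereb_map: np.ndarray,
    spec: ThresholdSpec = ThresholdSpec(),
) -> LabelField:
    """Connectivity-driven Vim from M1 and contralateral-cerebellum maps.

    ``binarize(threshold_lower(threshold_upper(m1, 40) * threshold_lower(cereb, 30), 30))``.
    Both maps are flat mask fields on ``grid``.  May legitimately return an
    empty label field (zero identified Vim volume).
    """
    m1_map = np.asarray(m1_map, dtype=float)
    cereb_map = np.asarray(cereb_map, dtype=float)
    if m1_map.shape != (grid.n_voxels,) or cereb_map.shape != (grid.n_voxels,):
        raise ValueError("maps must be flat mask fields on the given grid")
    if (m1_map < 0).any() or (cereb_map < 0).any():
        raise ValueError("tract-density maps must be nonnegative")

    pop = spec.percentile_population
    if not (m1_map > 0).any() or not (cereb_map > 0).any():
        # tractography produced nothing for one target: empty Vim
        return LabelField(grid, np.zeros(grid.n_voxels, dtype=np.int8))

    m1_cut = threshold_upper(m1_map, spec.m1_upper_pct, pop)
    cereb_cut = threshold_lower(cereb_map, spec.cereb_lower_pct, pop)
    product = m1_cut * cereb_cut
    if not (product > 0).any():
        return LabelField(grid, np.zeros(grid.n_voxels, dtype=np.int8))
    final = threshold_lower(product, spec.product_lower_pct, pop)
    return LabelField(grid, (final > 0).astype(np.int8))
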