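"""Group-average Vim atlas, atlas-defined Vim, and the reliability screen.

The connectivity-driven Vim has limited reliability even on high-quality
data, so a mask only enters atlas construction (and only serves as a
training label) if it passes four criteria:

1. its volume exceeds 20 mm^3 (the nucleus is roughly 4 x 4 x 6 mm, so a
   much smaller segmentation suggests failure);
2. it contains a single connected component (the Vim is one nucleus per
   hemisphere);
3. its correlation with a reference Vim atlas exceeds 0.5 in native space;
4. its centre of mass lies within 4 mm of the reference-atlas centroid.

Criteria 3 and 4 discard segmentations that deviate excessively from the
group-average location while still allowing individual variability.  All
masks handed to :func:`build_group_average` must already live on a common
grid; spatial normalisation is an upstream concern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import AtlasPrior, LabelField, _require_same_grid
from .evaluation import binary_centroid, centroid_displacement, weighted_centroid

__all__ = [
    "ReliabilityReport",
    "build_group_average",
    "atlas_defined_vim",
    "connected_components",
    "check_reliability",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class ReliabilityReport:
    """Outcome of the four-criterion screen for one Vim mask."""

    volume_mm3: float
    n_components: int
    atlas_correlation: float
    centroid_distance_mm: float
    pass_volume: bool
    pass_single_component: bool
    pass_correlation: bool
    pass_distance: bool

    @property
    def pass_all(self) -> bool:
        return (
            self.pass_volume
            and self.pass_single_component
            and self.pass_correlation
            and self.pass_distance
        )

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["pass_all"] = self.pass_all
        return d


def build_group_average(masks: list[LabelField]) -> AtlasPrior:
    """Voxel-wise proportion of subjects labelling each voxel as Vim.

    All masks must share one grid.  The result is the group-average Vim
    probability map ``g`` with ``g(v) = (# masks labelling v) / n``.
    """
    if not masks:
        raise ValueError("need at least one mask")
    grid = masks[0].grid
    for m in masks[1:]:
        _require_same_grid(grid, m.grid, "build_group_average")
    g = np.mean([m.y for m in masks], axis=0)
    return AtlasPrior(grid, g)


def atlas_defined_vim(prior: AtlasPrior, threshold: float = 0.5) -> LabelField:
    """Threshold the group-average probability map (at 0.5 by default)."""
    return LabelField(prior.grid, (prior.g >= threshold).astype(np.int8))


def connected_components(mask: LabelField, connectivity: int = 26) -> int:
    """Number of connected components under 6/18/26-connectivity."""
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    dense = mask.grid.dense_from_flat(mask.y.astype(float)) > 0
    _, n = ndimage.label(dense, structure=_STRUCTURES[connectivity])
    return int(n)


def check_reliability(
    vim: LabelField,
    atlas_native: AtlasPrior,
    min_volume_mm3: float = 20.0,
    min_corr: float = 0.5,
    max_dist_mm: float = 4.0,
    connectivity: int = 26,
    centroid_threshold: float = 0.1,
) -> ReliabilityReport:
    """Apply the four-criterion reliability screen to one Vim mask.

    Inequalities are strict, following the criteria's wording ("exceeds",
    "within").  The mask centroid is the unweighted mean of labelled voxel
    mm coordinates; the atlas centroid is probability-weighted after a low
    0.1 threshold.  The correlation is Pearson's r between the binary mask
    and the atlas probabilities over the mask voxels.  An empty mask fails
    everything, with an infinite centroid distance.
    """
    _require_same_grid(vim.grid, atlas_native.grid, "check_reliability")
    volume = vim.volume_mm3()

    if vim.is_empty:
        return ReliabilityReport(
            volume_mm3=0.0,
            n_components=0,
            atlas_correlation=0.0,
            centroid_distance_mm=np.inf,
            pass_volume=False,
            pass_single_component=False,
            pass_correlation=False,
            pass_distance=False,
        )

    n_comp = connected_components(vim, connectivity)

    y = vim.y.astype(float)
    g = atlas_native.g
    if y.std() == 0 or g.std() == 0:
        corr = 0.0
    else:
        corr = float(np.corrcoef(y, g)[0, 1])

    c_vim = binary_centroid(vim)
    c_atlas = weighted_centroid(atlas_native, threshold=centroid_threshold)
    dist = centroid_displacement(c_vim, c_atlas)

    return ReliabilityReport(
        volume_mm3=float(volume),
        n_components=n_comp,
        atlas_correlation=corr,
        centroid_distance_mm=float(dist),
        pass_volume=volume > min_volume_mm3,
        pass_single_component=n_comp == 1,
        pass_correlation=corr > min_corr,
        pass_distance=dist < max_dist_mm,
    )
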