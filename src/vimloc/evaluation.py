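"""Segmentation evaluation: Dice, centroid displacement, and comparisons.

Two metrics quantify agreement between a predicted Vim and a gold standard.
The Dice coefficient ``2|A n B| / (|A| + |B|)`` measures volumetric overlap
(probability maps are binarised first, default threshold 0.5).  Centroid
displacement — the Euclidean mm distance between cluster centroids — is
less sensitive to the binarisation threshold and is the clinically
meaningful quantity for stereotactic targeting.  Probabilistic centroids
are posterior-weighted after discarding voxels below 0.1; binary centroids
are plain voxel-coordinate means.  An empty segmentation has no centroid:
its displacement from anything is reported as infinity.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import AtlasPrior, LabelField, ProbabilityField, _require_same_grid

EMPTY = None  # sentinel for "no centroid": an empty segmentation

__all__ = [
    "EvalRecord",
    "dice",
    "weighted_centroid",
    "binary_centroid",
    "centroid_displacement",
    "point_overlap_probability",
    "compare_methods",
    "run_experiment",
]

METHODS = ("hq_augmentation", "connectivity_driven", "atlas_defined", "hq_vim")


@dataclass(frozen=True)
class EvalRecord:
    """One (subject, method, reference) evaluation row."""

    subject_id: str
    method: str
    reference: str
    dice: float
    centroid_displacement_mm: float
    reliable_subset: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.dice <= 1.0:
            raise ValueError("dice must lie in [0, 1]")
        if self.centroid_displacement_mm < 0:
            raise ValueError("displacement must be nonnegative (or inf)")


def dice(a: LabelField, b: LabelField) -> float:
    """Dice coefficient ``2|A n B| / (|A| + |B|)`` between two masks.

    Two empty masks give 0 (an empty prediction never counts as success).
    """
    _require_same_grid(a.grid, b.grid, "dice")
    na, nb = a.n_labelled, b.n_labelled
    if na + nb == 0:
        return 0.0
    inter = int(np.sum((a.y == 1) & (b.y == 1)))
    return 2.0 * inter / (na + nb)


def weighted_centroid(
    p: ProbabilityField | AtlasPrior, threshold: float = 0.1
) -> np.ndarray | None:
    """Probability-weighted centroid in mm, after a low-probability cut.

    Voxels with weight below ``threshold`` are discarded before averaging,
    eliminating voxels with a low likelihood of being Vim.  Returns the
    empty sentinel if nothing survives.
    """
    w = p.vim_probability if isinstance(p, ProbabilityField) else p.g
    keep = w >= threshold
    if not keep.any():
        return EMPTY
    coords = p.grid.mask_mm_coordinates()[keep]
    wk = w[keep]
    return coords.T @ wk / wk.sum()


def binary_centroid(m: LabelField) -> np.ndarray | None:
    """Unweighted mean mm coordinate of the labelled voxels."""
    if m.is_empty:
        return EMPTY
    coords = m.grid.mask_mm_coordinates()[m.y == 1]
    return coords.mean(axis=0)


def centroid_displacement(c1: np.ndarray | None, c2: np.ndarray | None) -> float:
    """Euclidean mm distance between centroids; infinity if either is empty."""
    if c1 is EMPTY or c2 is EMPTY:
        return np.inf
    return float(np.linalg.norm(np.asarray(c1) - np.asarray(c2)))


def point_overlap_probability(
    masks: Sequence[LabelField], point_mm: Sequence[float]
) -> float:
    """Proportion of subjects whose Vim mask contains the given mm location.

    The point is mapped to its nearest voxel under the grid affine; a point
    outside the grid is an error.
    """
    if not masks:
        raise ValueError("need at least one mask")
    grid = masks[0].grid
    idx = grid.mm_to_voxel(np.asarray(point_mm, dtype=float), round_to_int=True)
    if (idx < 0).any() or (idx >= np.asarray(grid.shape)).any():
        raise ValueError(f"point {point_mm} maps outside the grid")
    hits = 0
    for m in masks:
        _require_same_grid(grid, m.grid, "point_overlap_probability")
        dense = m.grid.dense_from_flat(m.y.astype(float))
        hits += int(dense[tuple(idx)] > 0)
    return hits / len(masks)


def compare_methods(
    paired: Mapping[str, tuple[np.ndarray, np.ndarray]],
    n_tests: int = 8,
) -> pd.DataFrame:
    """Paired t-tests with Bonferroni correction across comparisons.

    ``paired`` maps a comparison name to a pair of per-subject metric
    arrays (same subjects, same order).  Pairs containing non-finite
    values — e.g. the infinite displacement of an empty segmentation —
    are excluded from the test and counted in ``n_excluded``.  Adjusted
    p-values are ``min(1, p * n_tests)``.
    """
    rows = []
    for name, (a, b) in paired.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"{name}: unpaired samples")
        finite = np.isfinite(a) & np.isfinite(b)
        n_excl = int((~finite).sum())
        aa, bb = a[finite], b[finite]
        if len(aa) >= 2 and not np.allclose(aa, bb):
            t, p = stats.ttest_rel(aa, bb)
        elif len(aa) >= 2:
            t, p = 0.0, 1.0
        else:
            t, p = np.nan, np.nan
        rows.append(
            dict(
                comparison=name,
                n=len(aa),
                n_excluded=n_excl,
                mean_difference=float(np.mean(aa - bb)) if len(aa) else np.nan,
                t_statistic=float(t),
                p_value=float(p),
                p_adjusted=float(min(1.0, p * n_tests)) if np.isfinite(p) else np.nan,
            )
        )
    return pd.DataFrame(rows)


def _as_label(seg, threshold: float) -> LabelField:
    if isinstance(seg, ProbabilityField):
        return seg.binarize(threshold)
    if isinstance(seg, LabelField):
        return seg
    raise TypeError(f"expected LabelField or ProbabilityField, got {type(seg)}")


def _segment_centroid(seg) -> np.ndarray | None:
    if isinstance(seg, ProbabilityField):
        return weighted_centroid(seg, threshold=0.1)
    return binary_centroid(seg)


def run_experiment(
    subject_ids: Sequence[str],
    predictions: Mapping[str, Sequence[LabelField | ProbabilityField]],
    gold: Sequence[LabelField],
    reference_name: str = "truth",
    reliable: Sequence[bool] | None = None,
    dice_threshold: float = 0.5,
) -> pd.DataFrame:
    """Evaluate each method against the designated gold standard.

    ``predictions`` maps method name -> per-subject segmentations (aligned
    with ``subject_ids`` and ``gold``).  Probability maps are binarised at
    ``dice_threshold`` for Dice and use the 0.1-threshold weighted centroid
    for displacement; binary maps use the unweighted centroid.  Returns a
    tidy table of :class:`EvalRecord` rows.
    """
    if reliable is None:
        reliable = [True] * len(subject_ids)
    records = []
    for method, segs in predictions.items():
        if len(segs) != len(subject_ids):
            raise ValueError(f"{method}: prediction count != subject count")
        for sid, seg, ref, rel in zip(subject_ids, segs, gold, reliable):
            rec = EvalRecord(
                subject_id=sid,
                method=method,
                reference=reference_name,
                dice=dice(_as_label(seg, dice_threshold), ref),
                centroid_displacement_mm=centroid_displacement(
                    _segment_centroid(seg), _segment_centroid(ref)
                ),
                reliable_subset=bool(rel),
            )
            records.append(asdict(rec))
    return pd.DataFrame(records)
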