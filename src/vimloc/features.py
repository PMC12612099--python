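"""Feature engineering for the HQ-augmentation model.

The model input is built from named tract-density maps in four steps:

1. each map is normalised by its maximum density value;
2. interaction products are appended — every M1-related map (M1 target plus
   the thalamo-M1 white-matter segments) multiplied voxel-wise by every
   cerebellum-related map (cerebellothalamic-tract segments and the
   contralateral cerebellum), capturing the intersection of the
   dentato-thalamo-cortical pathway within the thalamus;
3. polynomial expansion with powers (2, 0.5, 0.2) plus the group-average
   Vim-prior column, giving ``phi(x_i) = [x, x^2, x^0.5, x^0.2, g_i]`` of
   dimension ``d' = 4 d + 1``;
4. per-subject standardisation (demean, unit variance) of every non-prior
   column across the subject's thalamic voxels.

Expansion is applied to the raw normalised densities in [0, 1] *before*
standardisation: the fractional powers are undefined on negative z-scores,
so the reverse order is not possible.  The prior column is a calibrated
probability and is passed through unscaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AtlasPrior, ConnectivityFeatureSet, VoxelGrid, _require_same_grid

DEFAULT_POWERS = (2.0, 0.5, 0.2)

__all__ = [
    "DEFAULT_POWERS",
    "FeatureLayout",
    "ExpandedFeatureSet",
    "paper_scale_layout",
    "normalize_tract_density",
    "build_interaction_features",
    "expand_features",
    "standardize_per_subject",
]


@dataclass(frozen=True)
class FeatureLayout:
    """Names of the base tract-density maps and of the interaction factors.

    ``m1_related`` are the maps targeting ipsilateral M1 and the white-matter
    segments between thalamus and M1; ``cereb_related`` are the maps
    targeting the cerebellothalamic-tract segments and the contralateral
    cerebellum.  Interaction features are all pairwise products
    m1-related x cerebellum-related.
    """

    base_names: tuple[str, ...]
    m1_related: tuple[str, ...]
    cereb_related: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "base_names", tuple(self.base_names))
        object.__setattr__(self, "m1_related", tuple(self.m1_related))
        object.__setattr__(self, "cereb_related", tuple(self.cereb_related))
        base = set(self.base_names)
        missing = [n for n in (*self.m1_related, *self.cereb_related) if n not in base]
        if missing:
            raise ValueError(f"interaction factors not among base features: {missing}")
        if len(base) != len(self.base_names):
            raise ValueError("duplicate base feature names")

    @property
    def interaction_names(self) -> tuple[str, ...]:
        return tuple(
            f"{m}*{c}" for m in self.m1_related for c in self.cereb_related
        )

    @property
    def all_names(self) -> tuple[str, ...]:
        return self.base_names + self.interaction_names

    @property
    def n_total(self) -> int:
        return len(self.all_names)


def paper_scale_layout() -> FeatureLayout:
    """The full-scale feature inventory: 113 base maps + 30 interactions = 143.

    Base maps: 75 ipsilateral cortical targets (M1 among them) plus the
    contralateral cerebellar white matter, 23 thalamic white-matter bundle
    segments, 4 cerebellothalamic-tract (SCPCT) segments, 5 thalamo-M1 and
    5 thalamo-S1 white-matter segments.  The 6 M1-related maps times the
    5 cerebellum-related maps give the 30 interaction products.
    """
    cortical = tuple(f"CTX-{i:02d}" for i in range(1, 75)) + ("M1",)
    base = (
        cortical
        + ("CEREB-CONTRA",)
        + tuple(f"XTRACT-{i:02d}" for i in range(1, 24))
        + ("SCPCT-1", "SCPCT-2", "SCPCT-3", "SCPCT-brainstem")
        + tuple(f"M1-{i}" for i in range(1, 6))
        + tuple(f"S1-{i}" for i in range(1, 6))
    )
    m1_related = ("M1", "M1-1", "M1-2", "M1-3", "M1-4", "M1-5")
    cereb_related = ("SCPCT-1", "SCPCT-2", "SCPCT-3", "SCPCT-brainstem", "CEREB-CONTRA")
    return FeatureLayout(base, m1_related, cereb_related)


@dataclass
class ExpandedFeatureSet:
    """The ``V x d'`` expanded design matrix ``Phi`` with provenance."""

    grid: VoxelGrid
    Phi: np.ndarray
    raw_names: tuple[str, ...]
    powers: tuple[float, float, float]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.Phi = np.asarray(self.Phi, dtype=float)
        self.raw_names = tuple(self.raw_names)
        self.powers = tuple(float(p) for p in self.powers)
        d = len(self.raw_names)
        if self.Phi.shape != (self.grid.n_voxels, 4 * d + 1):
            raise ValueError(
                f"Phi must be (V, 4d+1) = ({self.grid.n_voxels}, {4 * d + 1}), "
                f"got {self.Phi.shape}"
            )
        if not np.isfinite(self.Phi).all():
            raise ValueError("expanded features contain non-finite values")

    @property
    def expanded_dim(self) -> int:
        return self.Phi.shape[1]

    @property
    def prior_column(self) -> np.ndarray:
        return self.Phi[:, -1]


def normalize_tract_density(density: np.ndarray) -> np.ndarray:
    """Normalise a tract-density field by its maximum density value.

    An all-zero map (tractography reached no voxel) is returned unchanged;
    negative values are rejected because tract densities are streamline
    counts.
    """
    density = np.asarray(density, dtype=float)
    if density.size == 0:
        raise ValueError("empty density field")
    if (density < 0).any():
        raise ValueError("tract densities must be nonnegative")
    m = density.max()
    if m == 0:
        return density.copy()
    return density / m


def build_interaction_features(
    features: ConnectivityFeatureSet, layout: FeatureLayout
) -> ConnectivityFeatureSet:
    """Append the M1-related x cerebellum-related product columns.

    Every product column is named ``"<m1>*<cereb>"``.  Since the factors are
    normalised to [0, 1], products stay in [0, 1].  Columns already present
    are not duplicated: calling this twice is an error (duplicate names).
    """
    missing = [
        n
        for n in (*layout.m1_related, *layout.cereb_related)
        if n not in features.feature_names
    ]
    if missing:
        raise KeyError(f"feature set is missing interaction factors: {missing}")
    cols = [features.column(m) * features.column(c)
            for m in layout.m1_related for c in layout.cereb_related]
    X = np.column_stack([features.X] + cols) if cols else features.X.copy()
    names = list(features.feature_names) + list(layout.interaction_names)
    return ConnectivityFeatureSet(features.grid, names, X)


def expand_features(
    features: ConnectivityFeatureSet,
    prior: AtlasPrior,
    powers: tuple[float, float, float] = DEFAULT_POWERS,
) -> ExpandedFeatureSet:
    """Polynomial expansion plus the group-average prior term.

    ``Phi = [X, X^p1, X^p2, X^p3, g]`` with default powers (2, 0.5, 0.2).
    Requires ``X`` in [0, 1] (fractional powers need nonnegative inputs).
    """
    _require_same_grid(features.grid, prior.grid, "expand_features")
    X = features.X
    p1, p2, p3 = powers
    Phi = np.concatenate(
        [X, X**p1, X**p2, X**p3, prior.g[:, None]], axis=1
    )
    return ExpandedFeatureSet(
        features.grid, Phi, tuple(features.feature_names), tuple(powers)
    )


def standardize_per_subject(phi: ExpandedFeatureSet) -> ExpandedFeatureSet:
    """Demean and variance-normalise each non-prior column across the mask.

    The subject's design matrix is its own mini-batch during training, so
    standardisation statistics are computed within subject.  Constant
    columns map to all-zeros rather than NaN; the prior column passes
    through unscaled.  Idempotent on non-constant columns.
    """
    if phi.grid.n_voxels < 2:
        raise ValueError("cannot standardise with fewer than 2 mask voxels")
    Phi = phi.Phi.copy()
    body = Phi[:, :-1]
    mu = body.mean(axis=0)
    sd = body.std(axis=0)
    nz = sd > 0
    body[:, nz] = (body[:, nz] - mu[nz]) / sd[nz]
    body[:, ~nz] = 0.0
    Phi[:, :-1] = body
    return ExpandedFeatureSet(
        phi.grid, Phi, phi.raw_names, phi.powers, standardized=True
    )
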