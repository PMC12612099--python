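# Methods

## Problem and approach

The ventral intermediate nucleus (Vim) of the thalamus is the standard
surgical target for tremor, but it has no intrinsic contrast on
conventional MRI. Two individual-level localisation strategies exist:

* **connectivity-driven**: threshold the tract-density maps from the
  thalamic seed to ipsilateral M1 (upper 40%) and to the contralateral
  cerebellum (lower 30%), multiply them, and binarise the product at a
  lower 30% cut. This tracks individual anatomy but collapses on
  clinical-quality diffusion data — with poor angular resolution the
  tractography often produces no surviving cluster at all;
* **atlas-defined**: threshold a group-average Vim probability map at 0.5
  in native space. Robust, but blind to individual anatomy.

This package implements the *HQ-augmentation* strategy: learn, from paired
high-/low-quality data, a mapping from an extended set of low-quality
connectivity features to the high-quality connectivity-driven Vim
("HQ-Vim"), so that low-quality data alone yields a localisation close to
what high-quality data would have given.

## Model

Voxel labels `y` (Vim / not Vim, K = 2) on the thalamic mask follow a
conditional random field

    P(y | X) = exp(−E(y | X)) / Z(X)
    E(y | X) = Σ_i ψ_u(y_i | x_i) + Σ_{(i,j) ∈ E} ψ_p(y_i, y_j | x_i, x_j)

with unary cost `ψ_u(k | x_i) = w_k · φ(x_i)` and pairwise cost
`ψ_p = ρ · μ(y_i, y_j) · exp(−γ ‖φ(x_i) − φ(x_j)‖²)`, where `μ` is the
Potts compatibility (0 for equal labels, 1 otherwise). The edge set pairs
each mask voxel with its 26-connected neighbours (configurable 6/18/26);
each unordered pair enters the energy once, which makes the mean-field
update below the exact variational fixed point.

The feature map `φ` is built in `features`:

1. every tract-density map is normalised by its maximum;
2. interaction products: each M1-related map × each cerebellum-related map
   (at full scale, 6 × 5 products on top of 113 base maps = 143 features);
3. polynomial expansion with powers (2, 0.5, 0.2) plus the group-average
   Vim prior `g_i` as a final column: `φ(x) = [x, x², x^0.5, x^0.2, g]`,
   dimension `d' = 4d + 1`. Expansion precedes standardisation because the
   fractional powers are undefined on negative z-scores;
4. per-subject standardisation of every non-prior column (the subject's
   feature matrix is its own training mini-batch). The prior column is a
   calibrated probability and passes through unscaled.

Marginals are approximated by parallel mean-field sweeps

    Q_i(k) ∝ exp(−ψ_u(k|x_i) − Σ_{j∈N(i)} Σ_l Q_j(l) ρ μ(k,l) k_ij)

initialised at the unary softmax; with ρ = 0 the first sweep is already
exact. Edge kernels are precomputed per subject and cached.

## Training

The objective is the regularised cross-entropy of the one-hot reference
labels under the mean-field marginals:
`L = Σ_subjects Σ_i Σ_k −t_ik log Q_i(k) + λ₁‖W‖₁ + λ₂‖W‖₂²` (the log is
clamped at 1e-12 to stay finite). Gradients are obtained by reverse-mode
differentiation through a fixed number of unrolled mean-field sweeps
(default 10) and verified against central finite differences (< 1e-4
relative error). `ρ` is parameterised as `exp(θ)` to stay nonnegative.

Each subject is one mini-batch; subject order is reshuffled per epoch by a
seeded generator, so training is bit-reproducible. The default optimiser
applies a diagonal (Adam-style) preconditioner: the polynomial power
blocks of `φ` are strongly collinear, and unpreconditioned descent crawls
along the resulting valleys — on our cohorts it stalled around 0.1 Dice
below what an L-BFGS logistic fit attains, whereas the preconditioned
minibatch scheme closes that gap. Plain momentum SGD remains available
(`optimizer="sgd"`).

Two numerical guards apply to `θ`: steps are clipped to ±0.1 and `ρ` is
bounded to [1e-6, 1]. Beyond weak coupling, mean-field floods connected
components, the marginals saturate, every gradient dies, and training
cannot recover; the bound keeps inference in the regime where we validate
mean-field against exact enumeration (total variation ≤ 0.05 for ρ ≤ 0.5).

Key defaults (set by convergence checks on the synthetic cohorts): 100
epochs, learning rate 0.05 decayed ×0.97 per epoch, λ₁ = 1e-4, λ₂ = 1e-3,
ρ init 0.1. `γ` defaults to the median heuristic (median edge similarity
0.5 over training edges); `select_gamma` provides a cross-validated grid
choice instead.

## Training labels, reliability screen, and prior

HQ-Vim labels come from the connectivity-driven recipe applied to each
training subject's high-quality features. Because that recipe is
unreliable even on good data, a label enters training (and the
group-average prior) only if it passes four criteria: volume > 20 mm³
(the nucleus is ≈ 4×4×6 mm), a single connected component, Pearson
correlation > 0.5 with a reference atlas over the mask, and a centre of
mass within 4 mm of the (0.1-thresholded, probability-weighted) atlas
centroid. The pipeline bootstraps the reference atlas from the cohort's
own non-empty labels; with real data a published Vim atlas resampled to
the native grid can be supplied instead. Inequalities are strict;
connected components use 26-connectivity by default.

## Evaluation

Dice `2|A∩B|/(|A|+|B|)` (probability maps binarised at 0.5 by default;
both-empty defined as 0) and centroid displacement in mm. Probabilistic
centroids are posterior-weighted after discarding voxels below 0.1; binary
masks use the plain voxel-coordinate mean. An empty segmentation has
infinite displacement; infinite pairs are excluded from paired t-tests and
counted separately. Method comparisons use paired t-tests with Bonferroni
correction (×8 by default, matching the full study's eight comparisons).

## Synthetic cohort

The generator emulates the statistical structure of thalamic tract-density
features directly — the package's contract starts at tract-density maps,
so no streamlines are simulated. Per subject (all on one 15×15×17 voxel,
1 mm grid with an ellipsoidal thalamic mask of ~1335 voxels):

* a planted ellipsoidal Vim, semiaxes (2, 2, 3) mm, centred at a canonical
  offset plus N(0, 0.75²) mm jitter truncated at 1.5 mm. The truncation
  models the "reliable" anatomy the screen is designed to keep: every
  planted nucleus satisfies all four criteria against the cohort's own
  group average (verified over 24 cohorts);
* positive features: compact radial bumps `max(0, 1 − r²/R²)` with
  multiplicative lognormal noise (σ = 0.25; tract densities are
  nonnegative and right-skewed). M1 and contralateral cerebellum use
  R = 3.6 mm, calibrated so the 40/30/30 recipe on clean features carves
  out a nucleus-sized cluster (HQ-Vim vs truth Dice ≈ 0.79 — the premise
  that HQ-Vim approximates the gold standard). White-matter segment
  features are broader (R = 6–7 mm) with small anchor offsets: easier
  targets that survive degradation and carry the compensating signal;
* negative features peak ~4 mm posterior (the S1 pattern); neutral
  features are smoothed random fields;
* interaction products of the 2 M1-related × 2 cerebellum-related maps
  (default desk scale: 24 features total; a full-scale preset reproduces
  the 143-feature inventory).

Degradation modes: `low_angular` zeroes each long-range (cortical /
cerebellar) feature column with probability 0.3 per subject — whole-tract
failure — and attenuates the survivors by U(0.3, 0.7) before adding
spatially correlated noise (sd 0.05, 3 mm correlation length) and
re-normalising (degraded maps are max-normalised downstream too, so
attenuation appears as SNR loss). `low_spatial` applies a 3D Gaussian blur
(default σ = 1.5 mm); `both` composes them. Noise is spatially correlated
because tractography errors are structured along tracts; white noise
leaves the percentile baseline's centroid implausibly precise.

What the simulator does *not* model: real streamline geometry, distance
correction, registration error, partial-volume effects, inter-subject
variability of the thalamic mask itself, or correlated failures across
features. Passing the synthetic study therefore shows the pipeline's
machinery — labels, screen, prior, training, inference, metrics — behaves
as designed under controlled conditions, not that the accuracy figures
transfer to real diffusion MRI.

## Study harness and problem sizes

`run_study` trains on 40 subjects and evaluates 20 held-out subjects
(low-angular degradation, dropout 0.3): the HQ-augmentation prediction
from LQ features against the connectivity-driven baseline on LQ features
and the atlas-defined Vim, with the planted truth (or HQ-Vim) as gold
standard; optionally a second model trained on HQ features measures
across-quality consistency (Dice between a subject's HQ- and LQ-feature
outputs, compared to the same quantity for the baseline by paired t-test).
These sizes keep the full test suite under a minute and the acceptance
script under about forty seconds on one CPU while leaving the orderings
stable across cohort seeds.

## Numerical choices and degenerate inputs

* percentile cuts use linear interpolation over the *nonzero* mask voxels
  (configurable); ties at the cut are kept; an all-zero map propagates to
  an empty Vim, which is a valid value, not an error;
* all-zero tract maps normalise to themselves; constant columns
  standardise to zeros, never NaN; single-voxel subjects are rejected for
  standardisation;
* exact enumeration refuses V > 15; mean-field stops at max |ΔQ| < 1e-6 or
  the iteration cap;
* both-empty Dice is 0 (an empty prediction never scores as success);
  mm-points map to voxels by nearest-voxel rounding under the affine;
* grid agreement between a subject's volumes is enforced on shape and
  affine to 1e-5, with errors naming both files.

## Known limitations

* The pairwise term contributes little on the synthetic cohorts (trained
  ρ ≈ 0.4–0.9 with near-zero marginal effect on Dice); its value on real,
  noisier label boundaries is untested here.
* The across-quality experiment shares the degradation model between
  training and test; generalisation across *different* degradation types
  (the transfer the full-scale study performs across acquisition
  protocols) is not exercised at desk scale.
* The reliability screen's reference atlas is bootstrapped from the cohort
  itself; with very small cohorts the correlation criterion becomes noisy.
* K = 2 throughout; multi-nucleus labelling is out of scope.
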