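# vimloc

Localisation of the thalamic **ventral intermediate nucleus (Vim)** — the
standard surgical target for tremor — from white-matter connectivity
features, for researchers working on tractography-based targeting of deep
brain structures. The Vim has no intrinsic contrast on conventional MRI;
on high-quality diffusion data it can be found as the thalamic region
maximally connected to ipsilateral M1 and the contralateral cerebellum,
but that recipe collapses on clinical-quality acquisitions.

`vimloc` implements three localisation strategies end to end:

* **HQ-augmentation** (the core): a conditional random field over thalamic
  voxels trained to reproduce high-quality reference segmentations from an
  extended set of low-quality tract-density features,
* the **connectivity-driven** percentile baseline (M1 map thresholded at
  its upper 40% × cerebellum map thresholded at its lower 30%, product
  binarised at a lower 30% cut), and
* the **atlas-defined** baseline (group-average Vim probability map
  thresholded at 0.5),

together with the four-criterion reliability screen for reference
segmentations, Dice / centroid-displacement evaluation, and a synthetic
cohort generator with planted ground truth so the whole pipeline runs
without any external data.

## Model

For voxel features `x_i` (max-normalised tract densities plus interaction
products), labels follow the Gibbs distribution

```
P(y | X) ∝ exp(−E(y | X)),
E(y | X) = Σ_i  w_{y_i}·φ(x_i)  +  Σ_{(i,j)∈E}  ρ μ(y_i,y_j) e^{−γ‖φ(x_i)−φ(x_j)‖²}
```

where `φ(x) = [x, x², x^0.5, x^0.2, g]` appends polynomial terms and the
group-average Vim prior `g`, `μ` is the Potts compatibility, and the edge
set joins 26-connected mask voxels. Marginals come from mean-field
iteration (exactly the independent softmax when ρ = 0, and verified
against exhaustive enumeration at small V); training minimises the
L1/L2-regularised cross-entropy against reference labels by per-subject
mini-batch gradient descent, with gradients backpropagated through the
unrolled mean-field sweeps. See `docs/methods.md` for the full account.

## Worked example

Generate a paired-quality cohort with a planted nucleus, train on 20
subjects, evaluate the three methods on the 10 held-out subjects against
the planted truth:

```python
from vimloc import CohortSpec, DegradationSpec, TrainingConfig, generate_cohort
from vimloc.workflow import run_study

subjects = generate_cohort(CohortSpec(
    n_subjects=30, seed=7,
    degradation=DegradationSpec(mode="low_angular", dropout_prob=0.3),
))
result = run_study(subjects[:20], subjects[20:], TrainingConfig(seed=0),
                   with_hq_model=False)
print(result.median_by_method("dice").round(3))
print(result.median_by_method("displacement").round(2))
```

prints

```
method
atlas_defined          0.674
connectivity_driven    0.530
hq_augmentation        0.765
Name: dice, dtype: float64
method
atlas_defined          0.95
connectivity_driven    0.41
hq_augmentation        0.21
Name: centroid_displacement_mm, dtype: float64
```

Read: with 30% of the long-range tracts lost to the degraded angular
resolution, the CRF trained on degraded features still overlaps the true
nucleus best (median Dice 0.77) and places its centroid within a fifth of
a millimetre of the truth, while the percentile baseline drops to 0.53
Dice (its displacement median here covers only the subjects where it
found a cluster at all) and the atlas, blind to individual anatomy, sits
about 1 mm off.

The same pipeline is scriptable from the shell:

```
vimloc simulate --out cohort --n-subjects 30 --seed 7
vimloc train    --cohort cohort/manifest.json --out model --seed 0
vimloc evaluate --cohort cohort/manifest.json --out eval --seed 0
```

plus `features`, `baseline`, `atlas build/screen` and `predict`
subcommands for working with your own NIfTI volumes (run
`vimloc --help`).

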