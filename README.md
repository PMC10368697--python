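# skelpatch

Skeleton-guided 3D patch pipeline for intracranial-aneurysm segmentation in
time-of-flight MR angiography (TOF-MRA), exercised end-to-end on synthetic
vascular phantoms.

## The problem

Intracranial aneurysms are focal bulges of cerebral arteries, often only a
few millimetres across. Segmenting them in a whole TOF-MRA volume is an
extreme class-imbalance problem: aneurysm voxels are a vanishing fraction of
the brain, and even of the vasculature. This package implements a pipeline
that attacks the imbalance in two stages:

1. **Geometric reduction.** The bright vascular tree is segmented and thinned
   to a one-voxel-wide centerline (threshold → large-component labeling →
   region growing → morphological closing → topology-preserving
   26-neighborhood thinning). Training patches of 64×64×64 voxels are sampled
   only along this skeleton, reducing the imbalance from the 3D brain level
   to the 1D vessel level. The patch mix is controlled exactly: for every
   aneurysm-containing (positive) patch, *k* ∈ {1…5} aneurysm-free (negative)
   patches are sampled (the 1:*k* ratio).
2. **Multi-task learning.** A 3D U-Net (channels doubling per pooling step,
   23 convolutional layers in the reference geometry) segments the aneurysm,
   while auxiliary classification heads on the decoder (global pooling +
   sigmoid, binary cross-entropy loss) predict whether the patch contains an
   aneurysm at all. The total loss is the average of the segmentation loss
   (soft Dice + Tversky focal + voxel cross-entropy) and the classifier loss,
   so patches without any lesion still supervise the shared features.

Evaluation uses the field's standard quantities: a patch-level panel
(accuracy, sensitivity, specificity, PPV, NPV) and the per-case Dice
similarity coefficient

    DSC = 2 |V_GT ∩ V_pred| / (|V_GT| + |V_pred|),

reported as mean ± std over aneurysm-bearing cases and stratified by lesion
size (< 5 mm, 5–10 mm, > 10 mm).

Clinical angiograms with expert annotations are private, so the package
ships a first-class phantom generator: curved bright tubes (radius 0.5–3 mm)
with ellipsoidal aneurysm bulges whose diameters follow the clinical size
mixture (overwhelmingly < 5 mm), multiplied by a smooth bias field and
corrupted with Rician noise at ~0.3 mm isotropic voxels. Every downstream
stage is tested against this known ground truth.

The network stack (3D convolutions, batch norm, PReLU, attention, Adam,
losses) runs on a small numpy reverse-mode autodiff engine included in
`skelpatch.nn`; every hand-written backward pass is gradient-checked against
finite differences in the test suite.

## Worked example

```python
from skelpatch.pipeline import desk_profile, run_experiment

cfg = desk_profile(n_cases=8, master_seed=7, ratio_sweep=(2,), aux_sweep=(True,))
report = run_experiment(cfg)
print(report[["ratio", "aux", "accuracy", "sensitivity", "dsc_mean"]])
```

which prints (one row per sweep cell):

```
   ratio   aux  accuracy  sensitivity  dsc_mean
0      2  True  0.833333          0.5  0.166584
```

Reading: the cohort of 8 phantoms is split by case into train/validation/
test; on the held-out test case's patch mix the auxiliary head classified
10 of 12 patches correctly (accuracy 0.83) but recalled only half of the
aneurysm-containing patches (sensitivity 0.5), and the voxel-level overlap
between predicted and true aneurysm was DSC ≈ 0.17 — the desk-scale
schedule (a few minutes of one CPU core) is a smoke-scale readout, far
short of convergence. Larger cohorts and longer schedules raise all three
numbers; `scripts/acceptance.py` runs the properly powered version.

A thin CLI mirrors the library: `skelpatch phantom`, `skelpatch preprocess`,
`skelpatch skeletonize`, `skelpatch sample`, `skelpatch run`,
`skelpatch predict`, `skelpatch evaluate` (see `--help`).

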