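# acpcnet

Automatic localization of the **anterior and posterior commissures (AC/PC)**
in T1-weighted MRI volumes by volumetric Gaussian-heatmap regression with a
dilated 3D residual network.

The AC–PC axis is the reference line of stereotactic neurosurgery planning:
deep-brain stimulation targets (STN, GPi, Vim, ...) are located by offsets
from the mid AC–PC point, so errors in these two landmarks propagate
directly into surgical targeting error. Manual AC/PC annotation is slow and
operator-dependent. `acpcnet` automates it for volumes that have been
rigidly pre-aligned to a template:

1. **Targets** — each training volume gets a heatmap with an isotropic
   Gaussian sphere (σ = 3 voxels, peak 1) at each landmark:
   `H(v) = max_l exp(−‖v − v_l‖² / 2σ²)`.
2. **Network** — a 20-layer dilated residual regressor (three stages of
   residual blocks, dilations 1/2/4, 3³ kernels, shape-preserving) maps
   image windows to heatmap windows. Implemented self-contained in NumPy
   with hand-derived backprop, RMSprop/Adam, RMSE/Huber losses and L1/L2
   regularization.
3. **Training** — patch-based with weighted sampling: window centers are
   drawn from a Gaussian-sphere prior over the template AC/PC, with
   orthogonal-view, flip and ±10% scaling augmentation.
4. **Extraction** — predicted heatmaps are masked to a region of interest
   around the template landmarks, smoothed, and the two strongest peaks are
   refined to sub-voxel coordinates; the more anterior point (greater RAS y)
   is labeled AC.
5. **Statistics** — 3D Euclidean errors, scaled-MAD outlier filtering
   (c = −1/(√2·erfc⁻¹(3/2)) ≈ 1.4826), ANOVA plus Bonferroni-corrected
   one-/two-tailed Welch t-tests for model comparison, and multi-annotator
   consensus with a 2 mm disagreement flag.

A procedural **phantom generator** produces brain-like volumes with known
AC/PC ground truth (head/brain ellipsoids, ventricle-like hypointensities,
hyperintense landmark blobs, rigid jitter, bias field, noise), so the whole
pipeline is developed and tested without any real MRI data. Volumes are
NIfTI; landmarks are 3D Slicer `.fcsv` fiducial files; everything internal
is RAS millimeters.

## Worked example

Train the desk-scale preset (8-channel network, 40 phantoms of 64³ voxels,
500 iterations of 16 windows, RMSE + L1 + RMSprop) and evaluate on 10
held-out phantoms:

```python
import numpy as np
from acpcnet import (PhantomParams, NetConfig, TrainConfig, ExtractConfig,
                     generate_cohort, train_model, infer_heatmap,
                     extract_landmarks, localization_errors)

train_cohort = generate_cohort(40, PhantomParams(shape=(64, 64, 64), seed=101))
test_cohort  = generate_cohort(10, PhantomParams(shape=(64, 64, 64), seed=202))

cfg = TrainConfig.desk(loss="rmse", regularizer="L1", optimizer="rmsprop", seed=7)
model, curve = train_model(train_cohort, cfg, NetConfig.desk())
print(f"loss first/last epoch: {np.mean(curve.train_loss[:50]):.3f} "
      f"-> {np.mean(curve.train_loss[-50:]):.3f}")

errs = {"AC": [], "PC": []}
for vol, truth in test_cohort:
    pred = extract_landmarks(infer_heatmap(model, vol), ExtractConfig())
    for lab, e in localization_errors(pred, truth).items():
        errs[lab].append(e)
for lab in errs:
    print(f"{lab}: {np.mean(errs[lab]):.2f} ± {np.std(errs[lab], ddof=1):.2f} mm "
          f"(max {np.max(errs[lab]):.2f})")
```

Output of this exact run:

```
loss first/last epoch: 0.109 -> 0.043
AC: 0.22 ± 0.12 mm (max 0.39)
PC: 0.26 ± 0.07 mm (max 0.39)
```

The training loss (RMSE on heatmap windows plus the L1 penalty) falls by
more than half, and the held-out 3D localization error is sub-millimeter
for both commissures — the desk-scale analogue of the accuracy regime this
kind of pipeline targets on real MRI (on phantoms the landmarks are
procedurally image-predictable, so this does not certify clinical accuracy;
see `docs/methods.md`).

The same pipeline is scriptable from the shell:

```bash
acpcnet run --seed 1 --workdir runs/demo          # simulate ... evaluate
acpcnet simulate --config my.toml                 # individual stages
```

Stages share a TOML config (training keys use the patch-based framework
vocabulary: `spatial_window_size`, `batch_size`, `lr`, `decay`,
`loss_type`, `regularisation`, `optimiser`, `max_iter`) and a cohort
manifest CSV that accumulates volume, fiducial, heatmap and prediction
paths as stages run.

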