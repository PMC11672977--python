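# hemseg

Simultaneous segmentation of **intracerebral hemorrhage (ICH)** and
**perihematomal edema (PHE)** on non-contrast head CT, with individual-level
prediction-uncertainty scoring.

Hematoma and surrounding edema volumes are the key imaging markers of
primary and secondary brain injury in hemorrhagic stroke; quantifying them
quickly and reliably matters for prognosis, treatment selection and trial
enrollment.  `hemseg` implements the full pipeline a deployment needs:

* **Preprocessing** — Hounsfield-threshold skull stripping ([0, 200] HU plus
  morphological cleanup), brain windowing (level 40 / width 80 HU → [0, 1]),
  foreground cropping, and resampling to a common spacing, with an
  invertible record so predictions map back to the native CT grid.
* **A dual-branch network** — a shifted-window transformer encoder–decoder
  and a convolutional U-Net run side by side; each emits class-probability
  maps at multiple resolutions (deep supervision) and the final prediction
  averages the two branches' full-resolution maps.  The network, its
  reverse-mode autodiff engine and the optimizers are pure numpy, seeded
  and deterministic.
* **Training** — combined loss `CE + (1 − soft Dice)` attached to every
  supervised output with geometrically decaying weights; SGD (Nesterov 0.99,
  lr 1e-2, weight decay 3e-5, polynomial decay) by default; patient-grouped
  k-fold cross-validation so baseline/follow-up scan pairs never straddle
  folds.
* **Inference** — overlapping sliding windows blended with Gaussian
  importance weights; argmax ties break toward background.
* **Uncertainty** — test-time augmentation: with V₀ the segmented class
  volume of the plain prediction and Vᵢ the volumes under n invertible
  augmentations (flips, ±10° rotations, 0.9–1.1 zooms),

      Uncertainty = (1/n) Σᵢ |Vᵢ − V₀| / (Vᵢ + V₀)   ∈ [0, 1],

  averaged over ICH and PHE per subject; high-scoring subjects are flagged
  for manual review.
* **Evaluation** — Dice, maximum Hausdorff distance (mm), and Volume
  Similarity `1 − |V_A − V_B|/(V_A + V_B)`, per case and as cohort
  summaries.
* **Synthetic phantoms** — seeded head-CT phantoms (skull shell, brain,
  ventricles, volume-matched hematoma blob, contiguous edema rim, optional
  intraventricular blood, HU noise, anisotropic spacing) with ground-truth
  labels, so every stage is trainable and testable without clinical data.

See `docs/methods.md` for the model details and design rationale.

## Worked example

Train the tiny configuration on a 50-case synthetic cohort (patient-grouped
split, fold 0 held out) and score the held-out cases with TTA uncertainty:

```python
from hemseg.experiments import scaled_learning_run

run = scaled_learning_run(seed=0, num_epochs=16)
print(run.history[["epoch", "val_dice_ich", "val_dice_phe"]].tail(3))
print(run.heldout[["case_id", "ich_dice", "phe_dice", "uncertainty"]].head(3))
```

```
 epoch  val_dice_ich  val_dice_phe
    14      0.976205      0.763839
    15      0.977019      0.770437
    16      0.976713      0.765617
 case_id  ich_dice  phe_dice  uncertainty
case0000  0.997821  0.432177     0.063018
case0002  0.997647  0.890625     0.062584
case0004  0.995536  0.575581     0.045983
```

Hemorrhage (bright, ~65 HU) saturates within a few epochs; edema (subtle,
~18 HU, a thin rim) emerges later and reaches Dice ≈ 0.77 on held-out
phantoms.  The `uncertainty` column is the TTA volume-divergence score: 0
means the augmentations did not change the measured volumes at all.  It
responds to augmentation-sensitive errors (fragile boundaries, weak
detections); see `docs/methods.md` for what it can and cannot detect.

The same pipeline is scriptable from the shell:

```bash
hemseg simulate --n 50 --out cohort/ --seed 7
hemseg train --data cohort/ --out run/ --fold 0 --seed 1
hemseg predict --model run/best.npz --in cohort/case0001_ct.nii.gz \
               --out seg.nii.gz --tta 8 --seed 7
hemseg evaluate --pred preds/ --gt cohort/ --out report.csv
```

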