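# tzs — transition-zone search-space reduction for small-bowel obstruction

In adhesion-related small-bowel obstruction (SBO), the *transition zone*
(TZ) is the point where dilated bowel upstream of the obstruction changes
to collapsed bowel downstream. Finding it on an abdominopelvic CT is the
key step of the radiological work-up — and a slow, variable one. `tzs`
implements a patch-based localization strategy: rather than trying to pin
the TZ to a voxel, it ranks sub-volumes of the abdomen so a radiologist
can inspect a small highlighted fraction of the scan at a controlled risk
of missing the TZ.

The package is aimed at researchers studying spatial-prior-augmented
detection on volumetric scans. Since clinical SBO datasets are not
publicly available, it ships a phantom generator that emulates the study
conditions end to end, so every stage is reproducible at desk scale on a
laptop CPU.

## Method

1. **Body ROI.** The abdominopelvic region of each scan is extracted as
   the tight bounding box of the largest connected component above an
   intensity threshold (Otsu by default).
2. **Registration and spatial prior.** All ROIs are registered onto a
   reference ROI with an axis-aligned affine (scale + translation — a
   bounding box determines nothing more). Summing each scan's registered
   TZ-box indicator gives a cohort heatmap; counting, per patch, the
   fraction of training scans whose TZ center falls inside gives the patch
   prior `P(patch contains a TZ center)`, floored at 1e-3.
3. **Patch classification.** The ROI is split into `k x k x k` patches
   (k = 3, 4, 5), each resampled to a fixed cubic side and labeled
   positive iff it contains an annotation-box center. A 3D CNN — four
   blocks of two 3x3x3 convolutions (ReLU + batch norm) and 2x2x2 max
   pooling, then two dense layers with 0.5 dropout and a sigmoid — is
   trained with balanced cross-entropy

       L = -mean( w+ · y · log p + w- · (1-y) · log(1-p) ),
       w+ = N / 2N+,  w- = N / 2N-,

   with translation (±30 mm) and zoom (0.8–1.2) augmentation of positive
   patches.
4. **Coupling and evaluation.** Per-patch scores are multiplied by the
   patch prior. Operating points come from the threshold maximizing the
   Youden index (sens + spec − 1) on validation; the clinical readout is
   the curve of highlighted-volume fraction versus the patch-level
   false-negative rate, for raw and coupled scores.

Coordinates everywhere: axis order `(z, y, x)`, 0-based voxel indices,
half-open boxes `[lo, hi)`; z increases caudally, x toward patient-left.
The nine classical abdominal regions (right/left hypochondriac +
epigastric; right/left lumbar + umbilical; right/left iliac + hypogastric)
are equal thirds of the ROI on z and x, ignoring y.

## Worked example

```python
from tzs.model import CNNConfig, TrainConfig
from tzs.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    n_patients=150, scans_per_patient_max=1, k=3, patch_side=32, seed=1,
    cnn=CNNConfig(base_channels=2, dense_units=(64, 32)),
    train=TrainConfig(max_epochs=10, patience=3, batch_size=16),
)
report = run_pipeline(config, out_dir="out")
m = report["metrics"]
print("AUROC raw      ", round(m["auroc_raw"], 3))
print("AUROC coupled  ", round(m["auroc_coupled"], 3))
print("volume @ FN<=10%, raw    ", round(m["volume_at_fn_raw"], 3))
print("volume @ FN<=10%, coupled", round(m["volume_at_fn_coupled"], 3))
```

On the seeded 150-phantom cohort this prints:

```
AUROC raw       0.951
AUROC coupled   0.948
volume @ FN<=10%, raw     0.294
volume @ FN<=10%, coupled 0.296
```

Read: pooling all test patches, the classifier separates TZ-containing
from TZ-free patches with AUROC 0.95; accepting a 10% chance of missing a
TZ patch, thresholding highlights ~29% of the abdominopelvic volume. On
this cohort draw the raw and coupled operating points land within one
patch-highlight of each other (the curve's resolution here is
1/(27 patches x 15 test scans) ~ 0.0025): with a coarse k = 3 partition
the classifier leaves few false positives for the prior to suppress, so
the coupling's volume saving is conditional on the partition and
classifier operating regime — see `docs/methods.md` for when it pays off.
Phantom runs are reproducible bit-for-bit from the master seed; a
different seed moves these numbers by a few points.

The same pipeline is scriptable from the shell:

```bash
tzs generate --n-patients 20 --seed 1 --out cohort/
tzs preprocess --in cohort --out rois/
tzs prior --train-manifest cohort/manifest.csv --k 3 --out prior/
tzs patches --manifest cohort/manifest.csv --k 3 --patch-side 32 --out patches/
tzs train --patches patches/patches.npz --out model/
tzs evaluate --model model --prior prior/patch_prior.csv \
    --test-manifest cohort/manifest.csv --out eval/
# or end-to-end:
tzs run --seed 1 --out out/
tzs compare --k 3 --k 4 --k 5 --seed 1 --out cmp/
```

## Layout

| module | role |
|---|---|
| `tzs.phantoms` | synthetic cohort generator + NIfTI/JSON/CSV I/O |
| `tzs.preprocess` | body-ROI extraction, axis-aligned affine registration |
| `tzs.prior` | region grid, cohort heatmap, patch prior |
| `tzs.patches` | partitioning, labels, trilinear resampling, augmentation, patient splits |
| `tzs.model`, `tzs.nn` | the 3D CNN, balanced loss, training loop |
| `tzs.evaluate` | coupling, AUROC/precision/Youden, volume-vs-FN curves |
| `tzs.pipeline`, `tzs.cli` | orchestration, YAML config, `tzs` command |

See `docs/methods.md` for modeling assumptions, parameter defaults, and
known limitations.
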