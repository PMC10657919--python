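# wsunet — weakly supervised U-Net for explainable lung-tumour detection

Convolutional classifiers for radiology are usually black boxes: they say
*"this CT patch contains tumour"* without saying where.  Post-hoc saliency
methods (Grad-CAM, integrated gradients, occlusion sensitivity) try to
reverse-engineer the decision, but their outputs are not probabilities and
are not causally tied to the prediction.

This package implements an alternative: a **weakly supervised U-Net
(WSUnet)** that is a segmentation network trained *only with image-level
labels*.  A U-Net f_θ maps a patch x ∈ ℝ^{H×W} to a voxel-probability map

    p_v = f_θ(x) ∈ [0, 1]^{H×W},

and the image-level prediction is the **global max-pool** of that map:

    P(y = 1 | x) = max_v p_v.

Because a single voxel probability *is* the image decision, training with
image-level binary cross-entropy (Adam, learning rate 0.001, flip/rotation
augmentation, patience-5 early stopping, patient-disjoint cross-validation)
teaches the network to localise: the voxel map is a full-resolution,
causally verifiable explanation — its maximum equals the prediction
exactly, bitwise.

The package contains everything needed to study this claim end to end on a
single CPU, with no external data:

| module | contents |
| --- | --- |
| `wsunet.phantom` | synthetic CT-like thorax volumes (HU intensities, two mirror-symmetric lungs, blobby lesions, optional rib confounders) with ground-truth masks |
| `wsunet.patches` | the weak-labelling protocol: ×0.001 HU scaling, 40 tumour-centred + 40 contralateral mirrored 128×128 axial patches per subject, any-tumour-voxel labelling |
| `wsunet.models` | WSUnet (487 k parameters) and a standard-CNN comparator sharing its encoder (1344 k), built on a small numpy autodiff engine (`wsunet.nn`) |
| `wsunet.training` | image-level training with the voxel-metric epoch trace, early stopping, 5-fold patient-disjoint cross-validation |
| `wsunet.saliency` | Grad-CAM (7th/9th convolutional layer), integrated gradients (10 steps), occlusion sensitivity (width 10), nearest-neighbour upsampling, joint display normalisation |
| `wsunet.metrics` | voxel precision/recall/dice at threshold 0.5, AUPR, expected calibration error; image accuracy/sensitivity/specificity/AUC; 500-replicate bootstrap centile CIs |
| `wsunet.pipeline` / `wsunet.cli` | a cached, checksummed simulate→sample→train→explain→evaluate pipeline and its `wsunet` command-line front end |

## Worked example

Generate a small phantom cohort, train a compact WSUnet on image labels
only, and evaluate its voxel map against the held-out masks:

```python
from wsunet.phantom import PhantomConfig, generate_cohort
from wsunet.patches import PatchSamplingConfig, assemble_dataset
from wsunet.models import build_wsunet, WSUnetConfig
from wsunet.training import TrainingConfig, WeaklySupervisedImageModel
from wsunet.metrics import evaluate_voxels, BootstrapConfig

phantoms = generate_cohort(
    PhantomConfig(volume_shape=(24, 96, 96), lesion_radius_range_vox=(3, 5), seed=7), 10)
dataset = assemble_dataset(phantoms, PatchSamplingConfig(
    patch_shape=(32, 32), n_tumour=8, n_contralateral=8,
    offset_coronal=20, offset_sagittal=20, seed=7))

model = WeaklySupervisedImageModel(
    dataset,
    lambda seed: build_wsunet(WSUnetConfig(input_shape=(32, 32, 1), depth=2,
                                           base_filters=8), seed=seed),
    TrainingConfig(max_epochs=12, patience_epochs=5, batch_size=16, seed=0),
)
results = model.fit()
print(results.summary())

x_val, y_val, masks = results.val_dataset.arrays()
report = evaluate_voxels(results.predict_voxels(x_val), masks,
                         bootstrap=BootstrapConfig(n_bootstraps=500, seed=0))
print(report.to_frame("validation", "wsunet voxels").to_string(index=False))
```

which prints:

```
Weakly supervised image classifier
==================================
architecture:          wsunet
trainable parameters:  29,641
train patches:         128 (8 subjects)
validation patches:    32 (2 subjects)
epochs run:            12
best validation loss:  0.2543
validation accuracy:   0.938
final voxel dice:      0.189
final voxel AUPR:      0.144

 partition        method    metric    value   ci_low  ci_high
validation wsunet voxels      aupr 0.144021 0.123113 0.170274
validation wsunet voxels precision 0.448454 0.371080 0.526866
validation wsunet voxels    recall 0.119342 0.102429 0.141838
validation wsunet voxels      dice 0.188516 0.167535 0.214090
validation wsunet voxels       ece 0.104887 0.094397 0.114176
```

Read this the way a radiology ML practitioner would: with *no voxel labels
in training*, the voxel map ranks tumour voxels far above the ~3%
positive-voxel prevalence (AUPR 0.14), and the 0.5-thresholded map is
precise but conservative (precision 0.45, recall 0.12) — the max-pooling
head only needs *one* confident voxel to call an image positive, so the
model under-segments rather than over-segments.  The bracketed columns are
2.5th/97.5th centiles of 500 patch-level bootstrap replicates.

The same study at larger scale — and the comparison against Grad-CAM,
integrated gradients and occlusion sensitivity applied to the standard
CNN — is run by the pipeline:

```bash
wsunet run --config config.yaml --out-dir run   # or: python -m wsunet.cli run ...
wsunet models summary --arch wsunet             # layer catalogue, 487 k parameters
```

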