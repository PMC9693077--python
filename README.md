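# hsiprep

A tested, reusable pipeline for comparing **preprocessing chains in medical
hyperspectral imaging (HSI)**, built for pixel-wise tumor classification
studies. Intra-operative and ex-vivo HSI promises label-free tissue
discrimination, but raw cubes carry sensor noise, specular glare, and large
inter-patient illumination differences; which normalization to apply before
classification is an open practical question. `hsiprep` implements the full
comparison loop — calibration, five standard preprocessing presets,
training-set reduction, linear-SVM classification under leave-one-patient-out
cross-validation (LOOCV), and F1/AUC/MCC evaluation — and exercises it
end-to-end on synthetic multi-patient phantoms, so every stage is verifiable
without access to clinical data.

## The method

**Calibration.** Raw counts `R` become percent reflectance using white
(~99% reflective target) and dark (closed shutter) references:

    C = 100 · (R − D_ref) / (W_ref − D_ref)

**Preprocessing presets.** After edge-band removal (noisy sensor extremes),
optional spectral subsampling, and glare removal (mean-reflectance threshold
followed by morphological opening and one dilation):

| Preset     | Additional steps                                    |
|------------|-----------------------------------------------------|
| Calibrated | none                                                |
| Filtered   | Gaussian smoothing along the spectral axis          |
| MinMax     | Filtered + global rescale `(C − min C)/(max C − min C)` to [0, 1] |
| SNV        | Filtered + per-spectrum standard normal variate     |
| MedFilter  | per-band spatial median filter + SNV                |

SNV maps each pixel spectrum `C_i` to `(C_i − C̄_i)/s_i` (sample sd, so mean 0
and sd 1 per spectrum), cancelling per-pixel additive and multiplicative
distortions; Min-Max scaling cancels a per-cube affine distortion.

**Training-set reduction.** Labelled spectra are heavily redundant. Per
class, K-Means finds `k` centroids (default 100) and, for each centroid, the
`m` class pixels with smallest spectral angle
`θ(a, b) = arccos(⟨a,b⟩ / (‖a‖‖b‖))` are kept, without replacement — exactly
`k·m` training pixels per class when the class is large enough (e.g. 1000
per class at `m = 10`, 2000 at `m = 20`).

**Classification and evaluation.** A linear SVM (one-vs-rest, box constraint
1) with monotone sigmoid score calibration produces per-pixel class
probabilities; LOOCV holds out all pixels of one patient per fold. Per-class
F1 = `2TP/(2TP+FP+FN)`, ROC AUC, and Matthews correlation coefficient
`(TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))` are aggregated as
mean ± sd across patients; paired two-tailed t-tests compare models.
Classification maps (tumor red, healthy green, …) and blue→red tumor
probability maps render the results.

**Synthetic phantoms.** `hsiprep.synthgen` generates multi-patient datasets
with smooth class-specific signatures at a guaranteed spectral-angle
separation, additive sensor noise, a log-normal per-patient multiplicative
factor, a smooth multiplicative illumination field, near-white glare blobs,
and unlabeled margin rings between class regions.

## Worked example

Six simulated patients, well-separated tissue signatures (0.3 rad), strong
inter-patient variability (log-sd 0.3); LOOCV tumor metrics per preset:

```python
import numpy as np
from hsiprep import synthgen, evaluate

spec = synthgen.PhantomSpec(
    image_height=40, image_width=40, n_bands=32,
    class_names=("TT", "HT"),          # tumor vs healthy tissue
    class_fractions=(0.25, 0.5),
    min_class_separation=0.3,          # radians between class signatures
    additive_noise_sd=2.0,             # reflectance %
    patient_scale_sd=0.3,              # log-sd of the per-patient factor
    seed=21,
)
dataset = synthgen.generate_dataset(spec, n_patients=6, seed=22)

for preset in ("calibrated", "minmax", "snv"):
    record = evaluate.run_loocv(
        dataset, preset, clusters_per_class=25, pixels_per_centroid=10, seed=0
    )
    print(f"{preset:>10}: tumor AUC {record.mean('auc', 'TT'):.3f}  "
          f"tumor F1 {record.mean('f1', 'TT'):.3f}")
```

```
calibrated: tumor AUC 1.000  tumor F1 1.000
    minmax: tumor AUC 1.000  tumor F1 1.000
       snv: tumor AUC 1.000  tumor F1 1.000
```

On a shape-separable phantom all presets saturate — a per-patient
multiplicative factor cannot reorder a linear classifier's scores within a
patient (see `docs/methods.md`). Where the presets genuinely diverge is on
sharp spatial detail: the spatial median filter in MedFilter erases
1-pixel-wide structures that Min-Max preserves:

```python
region = np.full((32, 32), 2, dtype=np.int64)   # healthy background
region[::6, :] = 1                               # 1-px-wide tumor lines
spec = synthgen.PhantomSpec(
    image_height=32, image_width=32, n_bands=24,
    class_names=("TT", "HT"), class_fractions=(0.1, 0.6),
    min_class_separation=0.25, additive_noise_sd=1.5,
    margin_px=0, glare_fraction=0.005, seed=300,
)
patients = [
    synthgen.generate_cube_from_labels(spec, region, f"P{i+1:02d}", seed=900 + i)
    for i in range(4)
]
dataset = synthgen.SyntheticDataset(spec=spec, patients=patients)
for preset in ("minmax", "medfilter"):
    record = evaluate.run_loocv(
        dataset, preset, clusters_per_class=10, pixels_per_centroid=5, seed=0
    )
    print(f"{preset:>10}: thin-line tumor F1 {record.mean('f1', 'TT'):.3f} "
          f"AUC {record.mean('auc', 'TT'):.3f}")
```

```
    minmax: thin-line tumor F1 1.000 AUC 1.000
 medfilter: thin-line tumor F1 0.437 AUC 0.765
```

## Command line

```
hsiprep simulate  --spec spec.yaml --patients 6 --seed 1 --out data/
hsiprep preprocess --cube data/P01/raw.img --dark data/P01/dark.csv \
                   --white data/P01/white.csv --preset snv --out out.img
hsiprep reduce    --dataset data/ --clusters 100 --per-centroid 10 --seed 1 --out red/
hsiprep evaluate  --patients 6 --presets calibrated,minmax,snv --seed 1 --out results.csv
hsiprep run       --patients 6 --seed 1 --out run/     # full pipeline + maps
```

Cubes are stored as ENVI header + raw binary (BSQ written; BSQ/BIL/BIP
read), masks as indexed PNG + JSON legend, configuration as YAML, metrics as
CSV.

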