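# Methods

This note documents the models and procedures implemented in `hsiprep`, the
defaults and why they were chosen, what the synthetic phantoms do and do not
emulate, and the numerical conventions used throughout.

## Pipeline model

The pipeline treats a hyperspectral acquisition as a cube `(rows, cols,
bands)` of raw sensor counts with an ascending wavelength axis, accompanied
by dark and white reference acquisitions and a per-pixel class-label mask.
The analysis question is comparative: *which preprocessing chain, applied
between calibration and classification, best supports pixel-wise tumor
discrimination across patients?* All stages are deterministic functions of
their inputs and an explicit seed.

### Calibration

`C = 100·(R − D_ref)/(W_ref − D_ref)` elementwise. References may be
per-band vectors (spatially uniform) or full cubes; both occur in practice
and the formula is elementwise either way. Calibration is affine and
monotone in `R`; any element with `W_ref ≤ D_ref` makes the references
unusable and raises rather than producing signed infinities.

### Preprocessing operators

- **Edge-band removal** keeps the closed wavelength interval
  `[keep_lo, keep_hi]` (defaults 550–950 nm); sensor sensitivity collapses at
  the range extremes and those bands are noise-dominated.
- **Spectral subsampling** selects indices uniformly over the band-index
  range with nearest-index rounding, first and last band always retained.
  Index selection (not averaging) is the default because the operation
  models an acquisition-rate reduction; mean-binning is available via the
  library API if a user wants anti-aliased subsampling.
- **Glare detection** thresholds the per-pixel mean reflectance (default 90
  on the 0–100 scale) and applies a morphological opening (square element,
  radius 1) followed by one extra dilation, so isolated bright speckle is
  dropped and the immediate neighbourhood of true glare is excluded too.
  The threshold stands in for a manual per-database choice; 90 works because
  tissue reflectance sits well below the ~100% white-reference level while
  specular pixels saturate near it. Glare pixels are *excluded* via the
  validity mask — never inpainted — and take no part in normalization
  statistics, training, or evaluation.
- **Gaussian spectral smoothing**: per-pixel 1-D convolution along bands,
  unit-sum kernel, sigma 2 bands, truncated at 4σ, reflect boundary. Sigma 2
  is mild enough to preserve broad tissue features; it is configurable.
- **Median spatial smoothing**: per-band 2-D median, default 3×3 (the
  smallest odd kernel — deliberately conservative, since spatial medians
  erase structures thinner than half the kernel), reflect boundary; invalid
  pixels are excluded from every window via a NaN-aware median.
- **Min-Max scaling** uses the global min/max over all valid-pixel elements
  of the cube, so the output attains 0 and 1 exactly and a per-cube affine
  distortion cancels. A per-band variant exists behind a flag because the
  global convention, while it follows the scalar min/max notation, is not
  the only reading used in the field.
- **SNV** standardizes each spectrum to mean 0 and *sample* (ddof = 1)
  standard deviation 1. Zero-variance spectra are flagged invalid instead of
  aborting the cube. SNV is idempotent and invariant under per-pixel affine
  maps `x ↦ a·x + b`, `a > 0`, which is exactly the distortion class it is
  meant to remove.

### Chain presets

Step order is fixed (band removal → optional subsampling → glare removal →
smoothing → normalization): *Calibrated* stops after glare removal;
*Filtered* adds spectral Gaussian smoothing; *MinMax* and *SNV* add their
normalization after the Gaussian; *MedFilter* applies the spatial median to
the calibrated cube and finishes with SNV. Each output cube carries an
append-only history of the steps applied, so a result's provenance is
auditable.

One ambiguity is worth recording: the "Filtered" chain is described in some
sources as both spatial and spectral smoothing, and elsewhere as spectral
Gaussian smoothing only. The preset implements the spectral-only reading;
the spatial median remains available as an explicit operator. Similarly,
whether spectral subsampling precedes or follows edge-band removal is not
fixed by any constraint we know; the default is removal-then-subsampling and
both orders are reachable through the API.

### Training-set reduction

Per class, K-Means (seeded k-means++, `n_init = 3`, 300-iteration cap,
Euclidean metric on the preprocessed spectra) produces `k` centroids
(default 100); centroids are then visited in order and each takes the
`m` not-yet-selected class pixels with smallest spectral angle to it, ties
broken by ascending original pixel index. Selection is without replacement
so the per-class count is exactly `min(class size, k·m)`; with replacement
the advertised counts (1000 or 2000 per class) would only be upper bounds.
The reduced set is a strict subset of the input pixels — no synthesis, no
duplication — and the reduction applies to the SVM training path only.

### Classifier

One linear SVM per class (one-vs-rest, box constraint C = 1), with a
monotone sigmoid fitted per class on the training decision scores to map
them to [0, 1]; per-pixel class probabilities are renormalized to sum to 1.
The sigmoid is fitted on the training data itself (no internal CV split):
cheap, deterministic, and sufficient for ranking-based metrics; its absolute
calibration quality is not relied upon anywhere. "Class prior" switches the
calibration between empirical class frequencies (default) and
balanced/uniform weighting. Hard labels use the closed rule `p ≥ threshold`
for a binary positive class and argmax otherwise. `optimize_threshold`
evaluates midpoints between consecutive distinct scores and returns the
candidate minimizing |sensitivity − specificity|, ties broken by higher
Youden J then lower threshold — the "balance sensitivity against
specificity" operating point. Any object with `fit`/`predict_proba` can be
plugged in place of the SVM, so patch-based deep models can reuse the whole
harness.

### Evaluation

Folds are leave-one-patient-out: all cubes of one patient form the test set
and every other patient's labelled valid pixels form the training pool
(reduction refitted per fold; no test-patient pixel can reach training).
Per-class F1, ROC AUC (one-vs-rest on the renormalized probability column)
and MCC are computed over the held-out patient's labelled valid pixels;
unlabeled, margin, and glare pixels are excluded. Aggregation is the
unweighted mean ± sd across patients — a deliberate choice: pixel-pooling
would let large acquisitions dominate, whereas the clinical question is
per-patient performance. A fold missing a class (or with no evaluable pixels
at all, e.g. a fully glare-masked patient) records missing metrics for it
and drops out of that class's mean. MCC uses the zero-factor → 0 continuity
convention; F1 with an all-zero denominator is 0, both with warnings. The
paired two-tailed t-test uses Student's t with n−1 df on per-patient
differences; all-zero differences give (t = 0, p = 1) and constant nonzero
differences give (±∞, 0) with a degeneracy warning. No multiple-testing
correction is applied across preset pairs; p-values are reported raw.

## Synthetic phantoms

`generate_patient_cube` renders a scene of contiguous class regions
(vertical strips by default, arbitrary geometry via
`generate_cube_from_labels`) with true reflectance

    reflectance(pixel, band) = f_patient · g(pixel) · s_class(band) + ε

where `f_patient ~ lognormal(0, patient_scale_sd)` is a per-patient
multiplicative factor, `g` is a multiplicative illumination field (white
noise smoothed at correlation length `illumination_smoothness`, scaled to
relative amplitude `illumination_amplitude`, default 0.05 — the amplitude is
a generator parameter because a correlation length alone does not determine
a field), `s_class` is a smooth per-class signature, and
`ε ~ N(0, additive_noise_sd²)`. The raw cube inverts the calibration
equation with synthetic per-band references (white near-saturating, dark
small), so calibrating the generated raw data recovers the encoded
reflectance to float precision and the noiseless scene to within the noise
level. Glare is injected as connected blobs of raw values at 0.97–1.03× the
white reference, totalling exactly `round(glare_fraction · pixels)` pixels.
Label masks erode each region by `margin_px` (default 1) so class boundaries
are separated by an unlabeled margin ring, mirroring margin annotations that
are excluded from evaluation.

Signatures are sums of a smooth baseline, a linear trend and 2–4 broad
Gaussian bumps, clipped to 2–60% reflectance. Three constraints make the
generator's separation knob honest, and were fixed as generator design
before the acceptance conditions were frozen:

1. the pairwise spectral-angle floor is enforced on both raw and
   standardized (mean-0/sd-1) signatures — two affine-related curves have a
   large raw angle yet collapse to one shape under SNV, which would make
   "separated" classes SNV-inseparable;
2. each signature has spectral sd ≥ 4 reflectance % (`min_contrast`) — SNV
   divides by the per-pixel sd, so a near-flat signature would turn into
   pure noise under SNV while real tissue curves always carry structure;
3. the 60% reflectance cap keeps tissue well below the glare level (~100%),
   so threshold-based glare detection remains meaningful even for patient
   factors around 2.

**What the phantoms do not emulate:** chromophore-level tissue optics,
wavelength-dependent scattering tilts, per-patient *additive* offsets,
push-broom scan-line artifacts, mixed-tissue pixels at class boundaries, and
ex-vivo degradation effects. Consequences below.

## What the directional experiments can and cannot show

A per-patient multiplicative factor `f > 0` maps every spectrum `x` to
`f·x`, and any linear score `w·x + b` to `f·(w·x) + b`. Within one LOOCV
fold `f` is constant, so the *ranking* of a linear classifier's scores over
a patient's pixels — and hence the fold's AUC — is invariant to the patient
factor. The same sign-preservation argument shows a multiplicative-only
perturbation never destroys linear separability of shape-distinct classes in
training. Under this generator's patient model (multiplicative scalar +
multiplicative field, as designed), the Calibrated preset therefore cannot
be *strictly* beaten on AUC by the normalization presets in a shape-separable
regime: the directional comparison "SNV and MinMax ≥ Calibrated under strong
patient variability" holds as parity at ceiling (all presets reach AUC 1.0
on the test conditions: two classes, angle floor 0.25 rad, noise sd 1.5%,
patient log-sd 0.3, illumination amplitude 0.1, ten replicates of a
4-patient study). The degradations that normalization repairs on clinical
data evidently involve effects outside this model — additive scattering
offsets, wavelength-dependent distortions, nonlinear sensor behaviour —
and passing this comparison on phantoms does not certify a gain on real
cubes.

The *strict* directional effect the phantoms do reproduce is the spatial
median filter's cost on sharp structures: on scenes with 1-pixel-wide tumor
lines (geometry below the 3×3 kernel's half-width), the MedFilter preset's
thin-line F1 collapses relative to MinMax (≈0.4 vs 1.0 in the shipped
test), because the median replaces each thin-structure pixel with its
background neighbourhood before the classifier ever sees it.

## Problem sizes and numerical conventions

The shipped tests and acceptance script run on deliberately small instances,
chosen as the smallest sizes at which each property is non-trivial: phantoms
of 32–40 px square with 24–32 bands, 4–6 patients, reduction at 10–25
clusters per class in the LOOCV studies, and the three reduction-count
targets at their study settings (100 clusters per class with 3000–5000
pixels per class, 24 bands). Tolerances: SNV/Min-Max identities at 1e-9;
oracle equivalences at 1e-12; analytic fixed points at float32-quantisation
level (1e-4 on a 0–100 scale). K-Means determinism comes from seeding
(`n_init = 3`); spectral-angle ties break by pixel index; all seeds flow
from explicit arguments and a dataset's per-patient seeds are spawned from a
single root sequence.

## Known limitations

- The sigmoid calibration is fitted on training scores without a holdout, so
  absolute probabilities are optimistic near the margins; thresholds tuned
  by `optimize_threshold` on training folds inherit that bias.
- Per-class AUC in multi-class problems is one-vs-rest on renormalized
  probabilities; one-vs-one AUC is not implemented.
- The ENVI reader supports the common header subset (BSQ/BIL/BIP, float32/
  float64/int16/uint16, byte order 0); exotic header features are rejected
  rather than guessed.
- The glare threshold is global and absolute; adaptive or per-cube manual
  thresholds must be supplied by the caller.
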