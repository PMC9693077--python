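"""Synthetic multi-patient hyperspectral phantoms.

Generates raw cubes, dark/white references and label masks with the
statistical structure a tissue-classification study has to cope with:
class-specific smooth reflectance signatures, additive sensor noise, a
log-normal multiplicative per-patient factor, a spatially smooth
multiplicative illumination field, specular glare blobs, and unbalanced
contiguous class regions separated by an unlabeled margin ring.

Every quantity flows from explicit seeds, so identical seeds give
bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .hsio import LabelMask, RawCube, ReferencePair
from .reduce import spectral_angle

__all__ = [
    "PhantomSpec",
    "SignatureError",
    "generate_signature_bank",
    "generate_patient_cube",
    "generate_cube_from_labels",
    "generate_pixel_dataset",
    "generate_dataset",
    "PatientCube",
    "SyntheticDataset",
]


class SignatureError(RuntimeError):
    """Raised when a signature bank meeting the separation floor cannot be drawn."""


def _smooth_signature(rng: np.random.Generator, wavelengths: np.ndarray) -> np.ndarray:
    """One smooth non-negative reflectance curve: baseline + 2-4 broad bumps."""
    lo, hi = wavelengths[0], wavelengths[-1]
    span = hi - lo
    # tissue reflectance sits far below the ~100% white-reference level,
    # so glare stays separable by threshold even under strong patient factors
    base = rng.uniform(10.0, 35.0)
    slope = rng.uniform(-8.0, 8.0)
    sig = base + slope * (wavelengths - lo) / span
    for _ in range(rng.integers(2, 5)):
        center = rng.uniform(lo, hi)
        width = rng.uniform(0.08, 0.3) * span
        amp = rng.uniform(-15.0, 20.0)
        sig = sig + amp * np.exp(-0.5 * ((wavelengths - center) / width) ** 2)
    return np.clip(sig, 2.0, 60.0)


def generate_signature_bank(
    n_classes: int,
    n_bands: int,
    min_separation: float = 0.15,
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
    max_tries: int = 200,
    min_contrast: float = 4.0,
) -> np.ndarray:
    """Draw ``n_classes`` smooth mean spectra with pairwise spectral angle
    at least ``min_separation`` radians.

    Candidates are drawn greedily; a candidate is kept only if its angle to
    every accepted signature clears the floor — both for the raw spectra and
    for their standardized (mean-0, sd-1) forms.  The second check matters:
    two spectra related by an affine map have a large raw angle yet collapse
    to the same shape under per-spectrum normalization, which would make the
    classes inseparable after SNV.  Fails after ``max_tries`` rejected
    candidates per slot, which signals an infeasible request (too many
    classes for the angular separation asked).

    ``min_contrast`` is the minimum spectral standard deviation (reflectance
    %) of each signature: tissue reflectance curves have pronounced spectral
    structure, and a near-flat signature would carry no shape information
    once per-spectrum normalization divides by its own (tiny) deviation.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if n_bands < 8:
        raise ValueError("need at least 8 bands for smooth signatures")
    if wavelengths is None:
        wavelengths = np.linspace(500.0, 1000.0, n_bands)
    rng = np.random.default_rng(seed)

    def standardized(s: np.ndarray) -> np.ndarray:
        return (s - s.mean()) / s.std(ddof=1)

    def separated(a: np.ndarray, b: np.ndarray) -> bool:
        return (
            spectral_angle(a, b) >= min_separation
            and spectral_angle(standardized(a), standardized(b)) >= min_separation
        )

    bank: list[np.ndarray] = []
    while len(bank) < n_classes:
        for _ in range(max_tries):
            cand = _smooth_signature(rng, wavelengths)
            if cand.std(ddof=1) < min_contrast:
                continue
            if all(separated(cand, s) for s in bank):
                bank.append(cand)
                break
        else:
            raise SignatureError(
                f"could not place signature {len(bank) + 1}/{n_classes} with "
                f"min pairwise angle {min_separation} rad after {max_tries} tries"
            )
    return np.stack(bank)


@dataclass
class PhantomSpec:
    """Parameters of one synthetic study condition.

    Reflectances are in percent (0-100 scale before normalization).
    ``patient_scale_sd`` is the standard deviation of the log of the
    per-patient multiplicative factor (log-normal, median 1).
    ``illumination_smoothness`` is the spatial correlation length (pixels) of
    the multiplicative illumination field; ``illumination_amplitude`` its
    relative strength.  ``class_fractions`` are area fractions; the remainder
    of the scene is unlabeled background tissue.
    """

    image_height: int = 48
    image_width: int = 48
    n_bands: int = 32
    wavelength_start: float = 500.0
    wavelength_end: float = 1000.0
    class_names: Sequence[str] = ("TT", "HT")
    signature_bank: np.ndarray | None = None
    min_class_separation: float = 0.15
    additive_noise_sd: float = 1.0
    patient_scale_sd: float = 0.1
    illumination_smoothness: float = 12.0
    illumination_amplitude: float = 0.05
    glare_fraction: float = 0.01
    class_fractions: Sequence[float] = (0.2, 0.5)
    margin_px: int = 1
    seed: int = 0
    wavelengths: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.wavelength_end <= self.wavelength_start:
            raise ValueError("wavelength axis must be increasing")
        self.wavelengths = np.linspace(
            self.wavelength_start, self.wavelength_end, self.n_bands
        )
        if len(self.class_names) != len(self.class_fractions):
            raise ValueError("one area fraction per class required")
        fr = np.asarray(self.class_fractions, dtype=float)
        if np.any(fr < 0) or np.any(fr > 1) or fr.sum() > 1 + 1e-12:
            raise ValueError("class_fractions must lie in [0,1] and sum to <= 1")
        if not 0.0 <= self.glare_fraction < 1.0:
            raise ValueError("glare_fraction must lie in [0, 1)")
        if self.signature_bank is None:
            self.signature_bank = generate_signature_bank(
                len(self.class_names),
                self.n_bands,
                self.min_class_separation,
                seed=self.seed,
                wavelengths=self.wavelengths,
            )
        self.signature_bank = np.asarray(self.signature_bank, dtype=float)
        if self.signature_bank.shape != (len(self.class_names), self.n_bands):
            raise ValueError("signature_bank must be (n_classes, n_bands)")
        for i in range(len(self.class_names)):
            for j in range(i + 1, len(self.class_names)):
                ang = spectral_angle(self.signature_bank[i], self.signature_bank[j])
                if ang < self.min_class_separation - 1e-12:
                    raise ValueError(
                        f"signatures {i} and {j} violate the separation floor "
                        f"({ang:.3f} < {self.min_class_separation})"
                    )

    @property
    def legend(self) -> dict[int, str]:
        return {i + 1: name for i, name in enumerate(self.class_names)}


@dataclass
class PatientCube:
    """One simulated acquisition plus the ground truth behind it."""

    raw: RawCube
    refs: ReferencePair
    mask: LabelMask
    truth: np.ndarray          # reflectance actually encoded in raw (with noise)
    clean_truth: np.ndarray    # noiseless reflectance (factor x field x signature)
    glare_truth: np.ndarray    # bool, pixels overwritten by glare
    patient_factor: float
    patient_id: str


def _layout_regions(spec: PhantomSpec) -> np.ndarray:
    """Contiguous class rectangles as vertical strips; 0 = unlabeled remainder."""
    h, w = spec.image_height, spec.image_width
    region = np.zeros((h, w), dtype=np.int64)
    col = 0
    for idx, frac in enumerate(spec.class_fractions, start=1):
        width = int(round(frac * w))
        if width == 0 and frac > 0:
            width = 1
        region[:, col : col + width] = idx
        col += width
    return region


def _erode_labels(region: np.ndarray, margin: int) -> np.ndarray:
    """Shrink each class region by ``margin`` pixels: the unlabeled ring
    between regions mirrors the margin class excluded from evaluation."""
    if margin <= 0:
        return region.copy()
    from scipy.ndimage import binary_erosion

    labels = np.zeros_like(region)
    structure = np.ones((2 * margin + 1, 2 * margin + 1), dtype=bool)
    for cid in np.unique(region):
        if cid == 0:
            continue
        core = binary_erosion(region == cid, structure=structure, border_value=True)
        labels[core] = cid
    return labels


def _illumination_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal((spec.image_height, spec.image_width))
    smooth = gaussian_filter(noise, sigma=spec.illumination_smoothness, mode="reflect")
    sd = smooth.std()
    if sd < 1e-12:
        return np.ones_like(smooth)
    return 1.0 + spec.illumination_amplitude * (smooth - smooth.mean()) / sd


def _glare_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Connected glare blobs totalling exactly round(glare_fraction * pixels).

    Blob side never exceeds sqrt(remaining), so the final count is exact.
    """
    h, w = spec.image_height, spec.image_width
    target = int(round(spec.glare_fraction * h * w))
    mask = np.zeros((h, w), dtype=bool)
    count = 0
    while count < target:
        remaining = target - count
        side = 3 if remaining >= 9 else (2 if remaining >= 4 else 1)
        r = int(rng.integers(0, h - side + 1))
        c = int(rng.integers(0, w - side + 1))
        mask[r : r + side, c : c + side] = True
        count = int(mask.sum())
    return mask


def _synthetic_references(spec: PhantomSpec) -> ReferencePair:
    """Per-band references: near-saturating white (~99% target), small dark."""
    b = spec.n_bands
    lam = np.linspace(0.0, 1.0, b)
    # gentle spectral shape of the lamp/sensor response
    white = 3600.0 + 400.0 * np.sin(np.pi * lam)
    dark = 90.0 + 20.0 * lam
    return ReferencePair(dark=dark, white=white)


def generate_cube_from_labels(
    spec: PhantomSpec,
    region: np.ndarray,
    patient_id: str,
    seed: int,
    patient_factor: float | None = None,
) -> PatientCube:
    """Render a raw cube from an arbitrary class-region map (0 = background).

    This is the scene renderer behind :func:`generate_patient_cube`; exposing
    it lets callers build phantoms with custom geometry (thin structures,
    checkerboards) while keeping the same noise / illumination / glare model.
    """
    rng = np.random.default_rng(seed)
    h, w, b = spec.image_height, spec.image_width, spec.n_bands
    if region.shape != (h, w):
        raise ValueError("region map must match the spec's spatial shape")

    if patient_factor is None:
        patient_factor = float(np.exp(rng.normal(0.0, spec.patient_scale_sd)))
    field2d = _illumination_field(spec, rng)

    # background (unlabeled) tissue: a fixed smooth curve distinct per spec seed
    bg_rng = np.random.default_rng(spec.seed + 987654321)
    background = _smooth_signature(bg_rng, spec.wavelengths)

    sigs = np.vstack([background, spec.signature_bank])  # row 0 = background
    clean = sigs[region] * (patient_factor * field2d)[..., None]
    noisy = clean + rng.normal(0.0, spec.additive_noise_sd, size=(h, w, b))
    noisy = np.clip(noisy, 0.0, None)

    refs = _synthetic_references(spec)
    dark, white = refs.dark, refs.white
    raw = dark + (noisy / 100.0) * (white - dark)

    glare = _glare_mask(spec, rng)
    if glare.any():
        # specular pixels saturate near the white reference level
        glare_scale = rng.uniform(0.97, 1.03, size=(int(glare.sum()), 1))
        raw[glare] = white[None, :] * glare_scale
        noisy[glare] = 100.0 * (raw[glare] - dark) / (white - dark)

    labels = _erode_labels(region, spec.margin_px)
    labels[glare] = 0
    mask = LabelMask(labels, spec.legend)
    raw_cube = RawCube(raw.astype(np.float32), spec.wavelengths, patient_id=patient_id)
    return PatientCube(
        raw=raw_cube,
        refs=refs,
        mask=mask,
        truth=noisy,
        clean_truth=clean,
        glare_truth=glare,
        patient_factor=patient_factor,
        patient_id=patient_id,
    )


def generate_patient_cube(
    spec: PhantomSpec, patient_id: str, seed: int
) -> PatientCube:
    """One patient's acquisition: raw cube, references and label mask."""
    region = _layout_regions(spec)
    return generate_cube_from_labels(spec, region, patient_id, seed)


def generate_pixel_dataset(
    n_classes: int,
    pixels_per_class: int,
    n_bands: int = 24,
    min_separation: float = 0.15,
    noise_sd: float = 1.5,
    seed: int = 0,
):
    """A flat labelled spectra set (no spatial layout) for training-set
    reduction and classifier experiments.

    Each class contributes ``pixels_per_class`` noisy copies of its bank
    signature; labels are 1..n_classes, all pixels nominally from one
    acquisition.
    """
    from .reduce import PixelDataset

    bank = generate_signature_bank(n_classes, n_bands, min_separation, seed=seed)
    rng = np.random.default_rng(seed + 1)
    labels = np.repeat(np.arange(1, n_classes + 1), pixels_per_class)
    spectra = bank[labels - 1] + rng.normal(0.0, noise_sd, (len(labels), n_bands))
    pids = np.full(len(labels), "P01", dtype=object)
    return PixelDataset(np.clip(spectra, 0.0, None), labels, pids)


@dataclass
class SyntheticDataset:
    """A multi-patient synthetic study."""

    spec: PhantomSpec
    patients: list[PatientCube]

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def summary(self):
        """Labelled-pixel counts per class per patient (pandas DataFrame)."""
        import pandas as pd

        rows = []
        for p in self.patients:
            rec = {"patient_id": p.patient_id, "patient_factor": p.patient_factor}
            rec.update(p.mask.counts())
            rows.append(rec)
        return pd.DataFrame(rows)


def generate_dataset(
    spec: PhantomSpec, n_patients: int, seed: int = 0
) -> SyntheticDataset:
    """Simulate ``n_patients`` independent acquisitions of the same scene.

    Each patient gets an independent multiplicative factor, illumination
    field, noise realization and glare pattern, derived from a seed sequence
    spawned from ``seed``.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients for an inter-patient study")
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_patients)
    patients = [
        generate_patient_cube(
            spec, patient_id=f"P{i + 1:02d}", seed=int(child.generate_state(1)[0] % (2**31))
        )
        for i, child in enumerate(children)
    ]
    return SyntheticDataset(spec=spec, patients=patients)
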