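"""Reflectance calibration and the five preprocessing chain presets.

Raw counts are converted to percent reflectance with white/dark references,
noisy edge bands are dropped, glare pixels are masked out by threshold +
morphological opening, and the spectra are optionally smoothed and
normalized.  The five presets compared by the pipeline are:

=========== =================================================================
Calibrated  calibration + edge-band removal (+ optional subsampling) + glare
            removal — no smoothing or normalization
Filtered    Calibrated + Gaussian smoothing along the spectral axis
MinMax      Filtered + global min-max scaling of the cube to [0, 1]
SNV         Filtered + standard-normal-variate normalization per spectrum
MedFilter   Calibrated + per-band spatial median filter + SNV
=========== =================================================================

Min-max scaling removes a per-cube multiplicative factor; SNV removes
per-pixel additive and multiplicative distortions (each output spectrum has
mean 0 and sample standard deviation 1).  Glare pixels are excluded
(``valid_mask`` False) from all statistics, never inpainted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import (
    binary_dilation,
    binary_erosion,
    gaussian_filter1d,
    median_filter,
)

from .hsio import RawCube, ReferencePair, ReflectanceCube

__all__ = [
    "CalibrationError",
    "calibrate",
    "remove_edge_bands",
    "subsample_bands",
    "detect_glare",
    "apply_glare_mask",
    "gaussian_spectral_smooth",
    "median_spatial_smooth",
    "minmax_scale",
    "snv_normalize",
    "ChainPreset",
    "PRESETS",
    "apply_chain",
]


class CalibrationError(ValueError):
    """Unusable dark/white references (white not above dark somewhere)."""


def calibrate(raw: RawCube, refs: ReferencePair) -> ReflectanceCube:
    """Convert raw counts to percent reflectance:
    ``C = 100 * (R - Dref) / (Wref - Dref)`` elementwise.

    References may be per-band vectors or full cubes. Raises
    :class:`CalibrationError` if any used ``Wref - Dref`` element is <= 0.
    """
    dark, white = refs.dark, refs.white
    denom = white - dark
    if np.any(denom <= 0):
        raise CalibrationError("white reference must exceed dark reference everywhere")
    values = 100.0 * (raw.values.astype(np.float64) - dark) / denom
    return ReflectanceCube(
        values,
        raw.wavelengths,
        patient_id=raw.patient_id,
        history=["calibrate"],
    )


def remove_edge_bands(
    cube: ReflectanceCube, keep_lo: float, keep_hi: float
) -> ReflectanceCube:
    """Drop noisy sensor-edge bands, keeping wavelengths in the closed
    interval ``[keep_lo, keep_hi]`` nm."""
    if keep_lo >= keep_hi:
        raise ValueError("keep_lo must be below keep_hi")
    keep = (cube.wavelengths >= keep_lo) & (cube.wavelengths <= keep_hi)
    if not keep.any():
        raise ValueError(
            f"no bands inside [{keep_lo}, {keep_hi}] nm on an axis spanning "
            f"[{cube.wavelengths[0]}, {cube.wavelengths[-1]}] nm"
        )
    return cube.with_values(
        cube.values[:, :, keep],
        f"remove_edge_bands[{keep_lo},{keep_hi}]",
        wavelengths=cube.wavelengths[keep],
    )


def subsample_bands(cube: ReflectanceCube, target_bands: int) -> ReflectanceCube:
    """Reduce the band count by uniform index selection.

    Picks ``target_bands`` indices uniformly spaced over the band index range
    (first and last band always retained, nearest-index rounding), e.g.
    826 -> 128 bands over the retained brain range gives a mean wavelength
    step of ~3.61 nm.
    """
    n = cube.n_bands
    if target_bands < 2:
        raise ValueError("target_bands must be at least 2")
    if target_bands > n:
        raise ValueError(f"cannot subsample {n} bands up to {target_bands}")
    idx = np.unique(np.round(np.linspace(0, n - 1, target_bands)).astype(int))
    return cube.with_values(
        cube.values[:, :, idx],
        f"subsample_bands[{target_bands}]",
        wavelengths=cube.wavelengths[idx],
    )


def detect_glare(
    cube: ReflectanceCube, threshold: float = 90.0, structuring_radius: int = 1
) -> np.ndarray:
    """Specular-glare mask by threshold + morphological opening.

    Candidate pixels have mean reflectance over bands >= ``threshold``.
    Opening (erosion then dilation) with a square element of side
    ``2*radius+1`` drops isolated bright speckle; one extra dilation also
    flags the immediate neighbourhood of each glare blob.
    """
    if threshold <= 0:
        raise ValueError("glare threshold must be positive")
    candidates = cube.values.mean(axis=2) >= threshold
    if not candidates.any():
        return np.zeros_like(candidates)
    size = 2 * structuring_radius + 1
    structure = np.ones((size, size), dtype=bool)
    opened = binary_dilation(binary_erosion(candidates, structure), structure)
    return binary_dilation(opened, structure)


def apply_glare_mask(cube: ReflectanceCube, glare: np.ndarray) -> ReflectanceCube:
    """Mark glare pixels invalid (excluded, not inpainted)."""
    return cube.with_values(
        cube.values, "glare_removal", valid_mask=cube.valid_mask & ~glare
    )


def gaussian_spectral_smooth(
    cube: ReflectanceCube, sigma_bands: float = 2.0
) -> ReflectanceCube:
    """Per-pixel 1-D Gaussian smoothing along the band axis.

    Unit-sum kernel truncated at 4 sigma, reflect boundary: a constant
    spectrum is unchanged and interior values of a linear ramp are preserved.
    """
    if sigma_bands <= 0:
        raise ValueError("sigma_bands must be positive")
    if cube.n_bands < 3:
        raise ValueError("spectral smoothing needs at least 3 bands")
    smoothed = gaussian_filter1d(
        cube.values, sigma=sigma_bands, axis=2, mode="reflect", truncate=4.0
    )
    return cube.with_values(smoothed, f"gaussian_spectral_smooth[{sigma_bands}]")


def median_spatial_smooth(cube: ReflectanceCube, kernel: int = 3) -> ReflectanceCube:
    """Per-band 2-D median filter with reflect boundary.

    Invalid (glare) pixels are excluded from every window; if all pixels are
    valid the fast scipy path is used, otherwise a NaN-aware sliding-window
    median is computed.  Invalid pixels themselves keep their original value
    (they stay excluded via ``valid_mask``).
    """
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError("median kernel must be odd and >= 3")
    h, w, _ = cube.shape
    if kernel > h or kernel > w:
        raise ValueError("median kernel larger than the image")
    if cube.valid_mask.all():
        out = median_filter(cube.values, size=(kernel, kernel, 1), mode="reflect")
    else:
        vals = cube.values.copy()
        vals[~cube.valid_mask] = np.nan
        pad = kernel // 2
        padded = np.pad(vals, ((pad, pad), (pad, pad), (0, 0)), mode="reflect")
        windows = np.lib.stride_tricks.sliding_window_view(
            padded, (kernel, kernel), axis=(0, 1)
        )  # (h, w, bands, k, k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
            out = np.nanmedian(windows.reshape(h, w, -1, kernel * kernel), axis=3)
        bad = ~np.isfinite(out)
        out[bad] = np.broadcast_to(cube.values, out.shape)[bad]
        out[~cube.valid_mask] = cube.values[~cube.valid_mask]
    return cube.with_values(out, f"median_spatial_smooth[{kernel}]")


def minmax_scale(cube: ReflectanceCube, per_band: bool = False) -> ReflectanceCube:
    """Scale the cube to [0, 1]: ``C' = (C - min(C)) / (max(C) - min(C))``.

    min/max are scalars over all valid-pixel elements of the whole cube
    (``per_band=True`` switches to per-band statistics).  The output attains
    both 0 and 1 on valid pixels.  A constant cube is degenerate and raises.
    """
    valid = cube.values[cube.valid_mask]
    if valid.size == 0:
        raise ValueError("no valid pixels to normalize")
    if per_band:
        lo = valid.min(axis=0)
        hi = valid.max(axis=0)
        if np.any(hi - lo <= 0):
            raise ValueError("constant band: min-max scaling is degenerate")
    else:
        lo, hi = valid.min(), valid.max()
        if hi - lo <= 0:
            raise ValueError("constant cube: min-max scaling is degenerate")
    scaled = (cube.values - lo) / (hi - lo)
    return cube.with_values(scaled, f"minmax_scale[per_band={per_band}]")


def snv_normalize(cube: ReflectanceCube) -> ReflectanceCube:
    """Standard-normal-variate normalization per pixel spectrum.

    Each spectrum is centred on its mean and divided by its sample standard
    deviation (ddof=1), so every output spectrum has mean 0 and sample sd 1;
    this cancels per-pixel additive offsets and multiplicative scalings.
    Zero-variance spectra are flagged invalid rather than aborting the cube.
    """
    if cube.n_bands < 2:
        raise ValueError("SNV needs at least 2 bands")
    mean = cube.values.mean(axis=2, keepdims=True)
    sd = cube.values.std(axis=2, ddof=1, keepdims=True)
    degenerate = sd[..., 0] <= 0
    safe_sd = np.where(sd > 0, sd, 1.0)
    out = (cube.values - mean) / safe_sd
    return cube.with_values(
        out, "snv_normalize", valid_mask=cube.valid_mask & ~degenerate
    )


@dataclass(frozen=True)
class ChainPreset:
    """One named preprocessing recipe with its step parameters.

    The step order is fixed: edge-band removal, optional spectral
    subsampling, glare removal, smoothing, normalization.
    """

    name: str
    keep_lo: float = 550.0
    keep_hi: float = 950.0
    subsample: int | None = None
    glare_threshold: float = 90.0
    glare_radius: int = 1
    sigma_bands: float = 2.0
    median_kernel: int = 3
    minmax_per_band: bool = dc_field(default=False)

    _CANONICAL = ("calibrated", "filtered", "minmax", "snv", "medfilter")

    def __post_init__(self) -> None:
        if self.name.lower() not in self._CANONICAL:
            raise ValueError(
                f"unknown preset '{self.name}'; valid: {', '.join(self._CANONICAL)}"
            )


PRESETS: dict[str, ChainPreset] = {
    name: ChainPreset(name)
    for name in ("calibrated", "filtered", "minmax", "snv", "medfilter")
}


def apply_chain(
    raw: RawCube, refs: ReferencePair, preset: ChainPreset | str, **overrides
) -> ReflectanceCube:
    """Run one full preprocessing chain on a raw cube.

    ``preset`` is a :class:`ChainPreset` or a preset name; keyword overrides
    replace individual preset parameters (e.g. ``sigma_bands=3``).
    """
    if isinstance(preset, str):
        preset = ChainPreset(preset, **overrides)
    elif overrides:
        from dataclasses import replace

        preset = replace(preset, **overrides)
    name = preset.name.lower()

    cube = calibrate(raw, refs)
    cube = remove_edge_bands(cube, preset.keep_lo, preset.keep_hi)
    if preset.subsample is not None:
        cube = subsample_bands(cube, preset.subsample)
    glare = detect_glare(cube, preset.glare_threshold, preset.glare_radius)
    cube = apply_glare_mask(cube, glare)

    if name == "calibrated":
        return cube
    if name == "filtered":
        return gaussian_spectral_smooth(cube, preset.sigma_bands)
    if name == "minmax":
        cube = gaussian_spectral_smooth(cube, preset.sigma_bands)
        return minmax_scale(cube, per_band=preset.minmax_per_band)
    if name == "snv":
        cube = gaussian_spectral_smooth(cube, preset.sigma_bands)
        return snv_normalize(cube)
    if name == "medfilter":
        cube = median_spatial_smooth(cube, preset.median_kernel)
        return snv_normalize(cube)
    raise ValueError(f"unknown preset '{preset.name}'")  # pragma: no cover
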