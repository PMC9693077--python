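"""Containers and file I/O for hyperspectral cubes, label masks and run configs.

A hyperspectral cube is a ``(rows, cols, bands)`` float array with an
ascending wavelength axis in nanometres.  Cubes are stored on disk in the
ENVI convention: a small text header (``.hdr``) next to a raw binary file.
Label masks are indexed PNGs with a JSON class legend; run configuration is
YAML.  All readers/writers are lossless round trips at float32 / exact
integer precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

__all__ = [
    "RawCube",
    "ReferencePair",
    "ReflectanceCube",
    "LabelMask",
    "EnviParseError",
    "read_cube",
    "write_cube",
    "read_mask",
    "write_mask",
    "RunConfig",
    "load_run_config",
]


class EnviParseError(ValueError):
    """Malformed ENVI header or inconsistent binary payload."""


def _check_axes(values: np.ndarray, wavelengths: np.ndarray) -> None:
    if values.ndim != 3:
        raise ValueError(f"cube must be 3-D (rows, cols, bands), got shape {values.shape}")
    if any(s <= 0 for s in values.shape):
        raise ValueError(f"cube dimensions must be positive, got {values.shape}")
    if len(wavelengths) != values.shape[2]:
        raise ValueError(
            f"{len(wavelengths)} wavelengths for {values.shape[2]} bands"
        )
    if len(wavelengths) > 1 and not np.all(np.diff(wavelengths) > 0):
        raise ValueError("wavelength axis must be strictly increasing")


@dataclass
class RawCube:
    """Raw sensor counts R, shape (rows, cols, bands)."""

    values: np.ndarray
    wavelengths: np.ndarray
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        _check_axes(self.values, self.wavelengths)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]


@dataclass
class ReferencePair:
    """Dark and white reference acquisitions.

    Stored as per-band vectors (spatially uniform references) or as full
    cubes matching the raw data's spatial shape.  The white reference is
    acquired from a ~99%-reflective target, the dark one with the shutter
    closed; calibration divides by their difference, so ``white > dark`` is
    required wherever references are used.
    """

    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark, dtype=np.float64)
        self.white = np.asarray(self.white, dtype=np.float64)
        if self.dark.shape != self.white.shape:
            raise ValueError("dark and white references must share a shape")
        if self.dark.ndim not in (1, 3):
            raise ValueError("references must be per-band vectors or full cubes")


@dataclass
class ReflectanceCube:
    """Calibrated reflectance C in percent (nominally 0-100 pre-normalization).

    ``valid_mask`` is False for glare-excluded or otherwise unusable pixels;
    those pixels carry no meaning downstream and are excluded from
    normalization statistics, training and evaluation.  ``history`` is an
    append-only provenance record of the processing steps applied.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    valid_mask: np.ndarray | None = None
    patient_id: str = ""
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        _check_axes(self.values, self.wavelengths)
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.values.shape[:2], dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.values.shape[:2]:
            raise ValueError("valid_mask shape must match cube spatial shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def with_values(self, values: np.ndarray, step: str, **kw) -> "ReflectanceCube":
        """Copy with new values and one more provenance entry."""
        out = replace(self, values=values, history=self.history + [step], **kw)
        return out


@dataclass
class LabelMask:
    """Per-pixel class ids; 0 means unlabeled."""

    class_id: np.ndarray
    legend: dict[int, str]

    def __post_init__(self) -> None:
        self.class_id = np.asarray(self.class_id)
        if not np.issubdtype(self.class_id.dtype, np.integer):
            raise ValueError("class ids must be integers")
        present = set(np.unique(self.class_id)) - {0}
        missing = sorted(int(i) for i in present if int(i) not in self.legend)
        if missing:
            raise ValueError(f"mask ids missing from legend: {missing}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.class_id.shape

    def counts(self) -> dict[str, int]:
        """Labelled pixel count per class name."""
        return {
            name: int(np.sum(self.class_id == cid))
            for cid, name in sorted(self.legend.items())
        }


# ---------------------------------------------------------------------------
# ENVI cube I/O
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {"4": np.float32, "5": np.float64, "2": np.int16, "12": np.uint16}
_ENVI_CODES = {np.dtype(np.float32): "4", np.dtype(np.float64): "5"}


def _parse_envi_header(text: str) -> dict:
    """Parse the simple `key = value` / `key = {list}` ENVI header grammar."""
    fields: dict[str, str] = {}
    body = text
    if body.lstrip().upper().startswith("ENVI"):
        body = body.lstrip()[4:]
    i = 0
    while i < len(body):
        eq = body.find("=", i)
        if eq == -1:
            break
        key = body[i:eq].strip().lower()
        rest = body[eq + 1 :].lstrip()
        consumed = eq + 1 + (len(body[eq + 1 :]) - len(rest))
        if rest.startswith("{"):
            close = rest.find("}")
            if close == -1:
                raise EnviParseError(f"unterminated {{}} value for '{key}'")
            value = rest[1:close]
            i = consumed + close + 1
        else:
            nl = rest.find("\n")
            nl = len(rest) if nl == -1 else nl
            value = rest[:nl]
            i = consumed + nl
        if key:
            fields[key] = value.strip()
    return fields


def write_cube(cube: RawCube | ReflectanceCube, path: str | Path) -> None:
    """Write a cube as ENVI header (`path`.hdr) + BSQ float32 binary (`path`)."""
    path = Path(path)
    values = np.asarray(cube.values, dtype=np.float32)
    rows, cols, bands = values.shape
    wl = ", ".join(f"{w:.6g}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )
    path.with_suffix(path.suffix + ".hdr").write_text(header)
    # BSQ: band-sequential = (bands, rows, cols) on disk
    values.transpose(2, 0, 1).tofile(path)


def read_cube(
    path: str | Path, *, as_reflectance: bool = False, patient_id: str = ""
) -> RawCube | ReflectanceCube:
    """Read an ENVI header+raw cube; returns values as (rows, cols, bands)."""
    path = Path(path)
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    if not hdr_path.exists():
        hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise EnviParseError(f"no ENVI header found for {path}")
    fields = _parse_envi_header(hdr_path.read_text())

    for req in ("samples", "lines", "bands", "interleave", "data type"):
        if req not in fields:
            raise EnviParseError(f"missing required header field '{req}'")
    cols, rows, bands = (int(fields[k]) for k in ("samples", "lines", "bands"))
    interleave = fields["interleave"].lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise EnviParseError(f"unknown interleave '{interleave}'")
    code = fields["data type"]
    if code not in _ENVI_DTYPES:
        raise EnviParseError(f"unsupported data type code '{code}'")
    dtype = _ENVI_DTYPES[code]

    raw = np.fromfile(path, dtype=dtype)
    if raw.size != rows * cols * bands:
        raise EnviParseError(
            f"binary holds {raw.size} values, header declares {rows * cols * bands}"
        )
    if interleave == "bsq":
        values = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        values = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:  # bip
        values = raw.reshape(rows, cols, bands)

    if "wavelength" in fields:
        wavelengths = np.array(
            [float(tok) for tok in fields["wavelength"].split(",") if tok.strip()]
        )
        if len(wavelengths) != bands:
            raise EnviParseError(
                f"{len(wavelengths)} wavelengths for {bands} bands in header"
            )
        if len(wavelengths) > 1 and not np.all(np.diff(wavelengths) > 0):
            raise EnviParseError("non-monotone wavelength list in header")
    else:
        wavelengths = np.arange(bands, dtype=float)

    if as_reflectance:
        return ReflectanceCube(values, wavelengths, patient_id=patient_id)
    return RawCube(values, wavelengths, patient_id=patient_id)


# ---------------------------------------------------------------------------
# Label mask I/O (indexed PNG + JSON legend)
# ---------------------------------------------------------------------------

def write_mask(mask: LabelMask, path: str | Path, legend_path: str | Path) -> None:
    arr = mask.class_id
    if arr.max(initial=0) > 255:
        raise ValueError("indexed PNG masks support at most 255 classes")
    img = Image.fromarray(arr.astype(np.uint8), mode="P")
    # explicit identity palette so PNG optimization cannot remap the indices
    img.putpalette([v for i in range(256) for v in (i, i, i)])
    img.save(Path(path))
    Path(legend_path).write_text(
        json.dumps({str(k): v for k, v in mask.legend.items()}, indent=2)
    )


def read_mask(path: str | Path, legend_path: str | Path) -> LabelMask:
    arr = np.asarray(Image.open(Path(path))).astype(np.int64)
    legend = {int(k): v for k, v in json.loads(Path(legend_path).read_text()).items()}
    return LabelMask(arr, legend)  # unknown indices rejected in __post_init__


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_PRESET_NAMES = ("calibrated", "filtered", "minmax", "snv", "medfilter")

_CONFIG_DEFAULTS: dict[str, object] = {
    "preset": "minmax",
    "keep_lo": 550.0,            # nm, edge-band removal window
    "keep_hi": 950.0,
    "subsample_bands": None,     # int or None (brain: 128)
    "glare_threshold": 90.0,     # mean reflectance %, 0-100 scale
    "glare_radius": 1,           # structuring-element radius, pixels
    "sigma_bands": 2.0,          # spectral Gaussian sigma, bands
    "median_kernel": 3,          # spatial median window, pixels
    "clusters_per_class": 100,
    "pixels_per_centroid": 10,
    "box_constraint": 1.0,
    "class_prior": "empirical",
    "decision_threshold": 0.5,
    "seed": 0,
}


@dataclass
class RunConfig:
    preset: str
    keep_lo: float
    keep_hi: float
    subsample_bands: int | None
    glare_threshold: float
    glare_radius: int
    sigma_bands: float
    median_kernel: int
    clusters_per_class: int
    pixels_per_centroid: int
    box_constraint: float
    class_prior: str
    decision_threshold: float
    seed: int

    def __post_init__(self) -> None:
        if self.preset not in _PRESET_NAMES:
            raise ValueError(
                f"unknown preset '{self.preset}'; valid presets: {', '.join(_PRESET_NAMES)}"
            )
        if self.class_prior not in ("empirical", "uniform"):
            raise ValueError("class_prior must be 'empirical' or 'uniform'")
        if not 0.0 <= self.decision_threshold <= 1.0:
            raise ValueError("decision_threshold must lie in [0, 1]")


def load_run_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML run config, fill defaults, reject unknown keys."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("run config must be a YAML mapping")
        data.update(loaded)
    data.update(overrides)
    unknown = sorted(set(data) - set(_CONFIG_DEFAULTS))
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    merged = {**_CONFIG_DEFAULTS, **data}
    return RunConfig(**merged)  # type: ignore[arg-type]
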