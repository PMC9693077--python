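"""Classification and probability map rendering.

Classification maps paint each predicted class in its database colour
(tumor red, healthy colon/esophagus/brain green, stomach pink, blood vessel
blue, background black); tumor-probability maps interpolate from pure blue
(p=0) through white to pure red (p=1).  Invalid (glare) pixels are rendered
in a reserved neutral grey.  Rendering is a pure function of its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "Palette",
    "PALETTES",
    "INVALID_COLOR",
    "render_classification_map",
    "render_probability_map",
    "save_image",
]

INVALID_COLOR = (128, 128, 128)  # reserved neutral for glare/invalid pixels


@dataclass(frozen=True)
class Palette:
    """Class-name -> RGB colour map; colours must be distinct."""

    colors: tuple  # tuple of (name, (r, g, b)) pairs

    def __post_init__(self) -> None:
        rgbs = [c for _, c in self.colors]
        if len(set(rgbs)) != len(rgbs):
            raise ValueError("palette colours must be distinct")
        if INVALID_COLOR in rgbs:
            raise ValueError("palette must not use the reserved invalid colour")

    def as_dict(self) -> dict[str, tuple[int, int, int]]:
        return dict(self.colors)

    def __getitem__(self, name: str) -> tuple[int, int, int]:
        return self.as_dict()[name]


PALETTES: dict[str, Palette] = {
    "colon": Palette((("CT", (0, 200, 0)), ("TT", (255, 0, 0)), ("margin", (255, 255, 0)))),
    "esophagogastric": Palette(
        (
            ("ET", (0, 200, 0)),
            ("TT", (255, 0, 0)),
            ("ST", (255, 105, 180)),
            ("margin", (255, 255, 0)),
        )
    ),
    "brain": Palette(
        (
            ("BT", (0, 200, 0)),
            ("TT", (255, 0, 0)),
            ("BV", (0, 0, 255)),
            ("BG", (0, 0, 0)),
        )
    ),
}


def render_classification_map(
    labels: np.ndarray,
    legend: dict[int, str],
    palette: Palette,
    valid_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pixel class colours; returns a uint8 (rows, cols, 3) image.

    ``labels`` holds class ids, ``legend`` maps ids to class names, and every
    predicted class must have a palette entry; invalid pixels get the
    reserved neutral colour.
    """
    labels = np.asarray(labels)
    colors = palette.as_dict()
    img = np.zeros(labels.shape + (3,), dtype=np.uint8)
    for cid in np.unique(labels):
        name = legend.get(int(cid))
        if name is None:
            raise KeyError(f"class id {cid} missing from the legend")
        if name not in colors:
            raise KeyError(f"class '{name}' missing from the palette")
        img[labels == cid] = colors[name]
    if valid_mask is not None:
        img[~np.asarray(valid_mask, dtype=bool)] = INVALID_COLOR
    return img


# Fixed-endpoint diverging interpolation: blue (0) -> white (0.5) -> red (1).
_BLUE = np.array([0, 0, 255], dtype=float)
_WHITE = np.array([255, 255, 255], dtype=float)
_RED = np.array([255, 0, 0], dtype=float)


def render_probability_map(
    probs: np.ndarray, valid_mask: np.ndarray | None = None
) -> np.ndarray:
    """Tumor-probability map on a blue (0) -> red (1) scale.

    Linear interpolation blue->white->red with pure-blue and pure-red
    endpoints; the red channel is non-decreasing and the blue channel
    non-increasing in p.  NaN or masked pixels render neutral.
    """
    probs = np.asarray(probs, dtype=float)
    finite = np.isfinite(probs)
    if np.any((probs[finite] < 0) | (probs[finite] > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    p = np.where(finite, probs, 0.0)[..., None]
    low = _BLUE + (_WHITE - _BLUE) * (2.0 * p)
    high = _WHITE + (_RED - _WHITE) * (2.0 * p - 1.0)
    img = np.where(p <= 0.5, low, high)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    img[~finite] = INVALID_COLOR
    if valid_mask is not None:
        img[~np.asarray(valid_mask, dtype=bool)] = INVALID_COLOR
    return img


def save_image(img: np.ndarray, path: str | Path) -> None:
    Image.fromarray(img, mode="RGB").save(Path(path))
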