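"""Training-set reduction: per-class K-Means centroids + spectral-angle ranking.

Labelled pixel spectra are redundant — thousands of near-identical spectra
per tissue class inflate SVM training time without improving the fit.  The
reduction clusters each class's spectra with K-Means (k clusters per class),
then keeps, for each centroid, the ``pixels_per_centroid`` class pixels with
the smallest spectral angle to that centroid, without replacement across
centroids.  With k=100 clusters this yields exactly
``100 * pixels_per_centroid`` training pixels per class whenever the class
is large enough (e.g. 10 per centroid -> 1000/class for a four-class brain
setting, 4000 in total; 20 per centroid -> 2000/class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "spectral_angle",
    "PixelDataset",
    "ReducedSet",
    "flatten_labeled_pixels",
    "reduce_training_set",
]


def spectral_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Spectral angle between two spectra in radians.

    ``arccos(<a,b> / (|a| |b|))`` clamped to [0, pi]; scale-invariant, which
    is what makes it suitable for comparing spectra under multiplicative
    illumination differences.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("spectra must be equal-length 1-D vectors of length >= 2")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("spectral angle undefined for a zero vector")
    cos = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.arccos(cos))


def _angles_to_centroid(spectra: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Vectorized spectral angles from every row of ``spectra`` to one centroid."""
    norms = np.linalg.norm(spectra, axis=1)
    cn = np.linalg.norm(centroid)
    norms = np.where(norms == 0, np.inf, norms)
    cos = np.clip(spectra @ centroid / (norms * cn), -1.0, 1.0)
    return np.arccos(cos)


@dataclass
class PixelDataset:
    """Flattened labelled spectra with provenance (patient, cube, row, col)."""

    spectra: np.ndarray            # (n_pixels, L)
    labels: np.ndarray             # class ids, int
    patient_ids: np.ndarray        # str per pixel
    coords: np.ndarray | None = None  # (n_pixels, 3): cube index, row, col

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.labels = np.asarray(self.labels)
        self.patient_ids = np.asarray(self.patient_ids)
        n = len(self.spectra)
        if len(self.labels) != n or len(self.patient_ids) != n:
            raise ValueError("spectra, labels and patient_ids must align")
        if self.coords is not None:
            self.coords = np.asarray(self.coords)
            if len(self.coords) != n:
                raise ValueError("coords must align with spectra")

    def __len__(self) -> int:
        return len(self.spectra)

    def subset(self, index: np.ndarray) -> "PixelDataset":
        return PixelDataset(
            self.spectra[index],
            self.labels[index],
            self.patient_ids[index],
            None if self.coords is None else self.coords[index],
        )

    @staticmethod
    def concatenate(parts: list["PixelDataset"]) -> "PixelDataset":
        have_coords = all(p.coords is not None for p in parts)
        return PixelDataset(
            np.vstack([p.spectra for p in parts]),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.patient_ids for p in parts]),
            np.vstack([p.coords for p in parts]) if have_coords else None,
        )


@dataclass
class ReducedSet(PixelDataset):
    """A reduced training set: a strict subset of the input pixels, each
    tagged with the centroid that selected it."""

    centroid_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    source_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def flatten_labeled_pixels(cube, mask, cube_index: int = 0) -> PixelDataset:
    """Extract the valid (non-glare) labelled pixels of one cube.

    ``cube`` is a ReflectanceCube, ``mask`` a LabelMask of matching spatial
    shape; unlabeled (id 0) and invalid pixels are dropped.
    """
    if mask.shape != cube.shape[:2]:
        raise ValueError("mask and cube spatial shapes differ")
    keep = (mask.class_id > 0) & cube.valid_mask
    rows, cols = np.nonzero(keep)
    spectra = cube.values[rows, cols, :]
    labels = mask.class_id[rows, cols]
    pids = np.full(len(rows), cube.patient_id, dtype=object)
    coords = np.stack([np.full(len(rows), cube_index), rows, cols], axis=1)
    return PixelDataset(spectra, labels, pids, coords)


def reduce_training_set(
    data: PixelDataset,
    clusters_per_class: int = 100,
    pixels_per_centroid: int = 10,
    seed: int = 0,
) -> ReducedSet:
    """Select the most representative pixels of each class.

    Per class: K-Means with ``clusters_per_class`` seeded k-means++ clusters
    (Euclidean on the preprocessed spectra, 300-iteration cap); for each
    centroid in turn, the class pixels are ranked by ascending spectral angle
    to the centroid and the best ``pixels_per_centroid`` not yet selected are
    taken (without replacement, ties broken by ascending original pixel
    index).  A class with fewer than ``clusters_per_class *
    pixels_per_centroid`` pixels is returned whole.  Deterministic given
    ``seed``.
    """
    if clusters_per_class < 1 or pixels_per_centroid < 1:
        raise ValueError("clusters_per_class and pixels_per_centroid must be >= 1")
    if len(data) == 0:
        raise ValueError("empty pixel dataset")

    classes = np.unique(data.labels)
    sel_index: list[np.ndarray] = []
    sel_centroid: list[np.ndarray] = []
    for ci, cls in enumerate(classes):
        cls_idx = np.nonzero(data.labels == cls)[0]
        if cls_idx.size == 0:
            raise ValueError(f"class {cls} has no pixels")
        spectra = data.spectra[cls_idx]
        budget = clusters_per_class * pixels_per_centroid
        if cls_idx.size <= budget:
            sel_index.append(cls_idx)
            sel_centroid.append(np.full(cls_idx.size, -1))
            continue
        km = KMeans(
            n_clusters=clusters_per_class,
            init="k-means++",
            n_init=3,
            max_iter=300,
            random_state=seed + ci,
        ).fit(spectra)
        taken = np.zeros(cls_idx.size, dtype=bool)
        order_base = np.arange(cls_idx.size)
        for k, centroid in enumerate(km.cluster_centers_):
            angles = _angles_to_centroid(spectra, centroid)
            ranking = np.lexsort((order_base, angles))  # angle, then index
            picked = ranking[~taken[ranking]][:pixels_per_centroid]
            taken[picked] = True
            sel_index.append(cls_idx[np.sort(picked)])
            sel_centroid.append(np.full(picked.size, k))

    index = np.concatenate(sel_index)
    centroid_ids = np.concatenate(sel_centroid)
    order = np.argsort(index, kind="stable")
    index, centroid_ids = index[order], centroid_ids[order]
    return ReducedSet(
        spectra=data.spectra[index],
        labels=data.labels[index],
        patient_ids=data.patient_ids[index],
        coords=None if data.coords is None else data.coords[index],
        centroid_ids=centroid_ids,
        source_index=index,
    )
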