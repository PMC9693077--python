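"""Metrics, leave-one-patient-out cross-validation and paired t-tests.

Per-class F1, ROC AUC and Matthews correlation coefficient are computed
one-vs-rest over the held-out patient's labelled valid pixels; folds are
aggregated as unweighted mean +/- standard deviation across patients (never
pixel-pooled, so a small patient counts as much as a large one).  The paired
two-tailed t-test compares two models' per-fold AUCs patient by patient.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .classify import ClassifierConfig, train_classifier
from .preprocess import ChainPreset, apply_chain
from .reduce import PixelDataset, flatten_labeled_pixels, reduce_training_set

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "f1_score",
    "mcc",
    "auc_roc",
    "FoldResult",
    "MetricRecord",
    "run_loocv",
    "paired_t_test",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts for one positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(truth: np.ndarray, pred: np.ndarray, positive) -> ConfusionCounts:
    t = np.asarray(truth) == positive
    p = np.asarray(pred) == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)),
    )


def f1_score(c: ConfusionCounts) -> float:
    """F1 = 2*TP / (2*TP + FP + FN); defined as 0 (with a warning) when the
    denominator vanishes (no positives anywhere)."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        warnings.warn("F1 undefined (no positive truth or predictions); returning 0")
        return 0.0
    return 2 * c.tp / denom


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient,
    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))`` in [-1, 1];
    any zero factor gives 0 by the continuity convention (with a warning)."""
    factors = [
        (c.tp + c.fp),
        (c.tp + c.fn),
        (c.tn + c.fp),
        (c.tn + c.fn),
    ]
    if any(f == 0 for f in factors):
        warnings.warn("MCC denominator has a zero factor; returning 0 by convention")
        return 0.0
    num = c.tp * c.tn - c.fp * c.fn
    return num / math.sqrt(math.prod(float(f) for f in factors))


def auc_roc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Area under the ROC curve for positive-class scores.

    Trapezoidal area, equivalently the Mann-Whitney pairwise statistic
    P(score+ > score-) + 0.5 P(equal).  Requires both classes present.
    """
    truth = np.asarray(truth).astype(bool).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if truth.all() or not truth.any():
        raise ValueError("AUC requires both classes in the truth labels")
    return float(roc_auc_score(truth, scores))


@dataclass
class FoldResult:
    """Per-class metrics for one held-out patient."""

    patient_id: str
    n_pixels: int
    f1: dict = field(default_factory=dict)       # class name -> value or NaN
    auc: dict = field(default_factory=dict)
    mcc: dict = field(default_factory=dict)
    confusion: dict = field(default_factory=dict)


@dataclass
class MetricRecord:
    """Mean +/- sd of each metric per class across folds (missing folds for a
    class are excluded from that class's aggregation)."""

    folds: list[FoldResult]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fold in self.folds:
            for metric in ("f1", "auc", "mcc"):
                for cls, val in getattr(fold, metric).items():
                    rows.append(
                        {
                            "patient_id": fold.patient_id,
                            "class": cls,
                            "metric": metric,
                            "value": val,
                        }
                    )
        return pd.DataFrame(rows)

    def aggregate(self) -> pd.DataFrame:
        df = self.to_frame().dropna(subset=["value"])
        agg = (
            df.groupby(["class", "metric"])["value"]
            .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
            .reset_index()
        )
        return agg

    def mean(self, metric: str, cls: str) -> float:
        agg = self.aggregate()
        row = agg[(agg["class"] == cls) & (agg["metric"] == metric)]
        if row.empty:
            raise KeyError(f"no aggregated value for {metric}/{cls}")
        return float(row["mean"].iloc[0])

    def fold_values(self, metric: str, cls: str) -> np.ndarray:
        return np.array(
            [getattr(f, metric).get(cls, np.nan) for f in self.folds], dtype=float
        )


def _fold_metrics(
    model, test: PixelDataset, legend: dict[int, str]
) -> tuple[dict, dict, dict, dict]:
    probs = model.predict_proba(test.spectra)
    pred = model.classes_[np.argmax(probs, axis=1)]
    f1_d, auc_d, mcc_d, conf_d = {}, {}, {}, {}
    for col, cls in enumerate(model.classes_):
        name = legend.get(int(cls), str(cls))
        present = np.any(test.labels == cls)
        if not present:
            f1_d[name] = auc_d[name] = mcc_d[name] = np.nan
            continue
        c = confusion_counts(test.labels, pred, cls)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1_d[name] = f1_score(c)
            mcc_d[name] = mcc(c)
        truth = test.labels == cls
        auc_d[name] = auc_roc(probs[:, col], truth) if not truth.all() else np.nan
        conf_d[name] = c
    return f1_d, auc_d, mcc_d, conf_d


def run_loocv(
    dataset,
    preset: ChainPreset | str,
    clf_config: ClassifierConfig | None = None,
    clusters_per_class: int = 100,
    pixels_per_centroid: int = 10,
    seed: int = 0,
    reduce_training: bool = True,
) -> MetricRecord:
    """Leave-one-patient-out evaluation of one preprocessing preset.

    Every cube is preprocessed once with the preset; each fold holds out all
    pixels of one patient for testing and trains on the remaining patients'
    labelled valid pixels (reduced by K-Means+SAM when ``reduce_training``),
    so no test-patient pixel ever reaches training.
    """
    clf_config = clf_config or ClassifierConfig(seed=seed)
    legend = dataset.spec.legend if hasattr(dataset, "spec") else {}

    per_patient: dict[str, list[PixelDataset]] = {}
    for i, p in enumerate(dataset.patients):
        cube = apply_chain(p.raw, p.refs, preset)
        px = flatten_labeled_pixels(cube, p.mask, cube_index=i)
        per_patient.setdefault(p.patient_id, []).append(px)

    patient_ids = list(per_patient)
    if len(patient_ids) < 2:
        raise ValueError("leave-one-patient-out needs at least 2 patients")

    folds: list[FoldResult] = []
    for pid in patient_ids:
        train_parts = [
            px for other, parts in per_patient.items() if other != pid for px in parts
        ]
        train = PixelDataset.concatenate(train_parts)
        if reduce_training:
            train = reduce_training_set(
                train, clusters_per_class, pixels_per_centroid, seed=seed
            )
        model = train_classifier(train, clf_config)
        test = PixelDataset.concatenate(per_patient[pid])
        if len(test) == 0:
            # a fully glare-masked (or unlabeled) test patient yields no
            # evaluable pixels; record the fold as missing rather than abort
            warnings.warn(f"fold {pid}: no labelled valid pixels to evaluate")
            nan_d = {name: np.nan for name in legend.values()}
            folds.append(
                FoldResult(patient_id=pid, n_pixels=0, f1=dict(nan_d),
                           auc=dict(nan_d), mcc=dict(nan_d), confusion={})
            )
            continue
        f1_d, auc_d, mcc_d, conf_d = _fold_metrics(model, test, legend)
        folds.append(
            FoldResult(
                patient_id=pid,
                n_pixels=len(test),
                f1=f1_d,
                auc=auc_d,
                mcc=mcc_d,
                confusion=conf_d,
            )
        )
    return MetricRecord(folds)


def paired_t_test(metric_a: np.ndarray, metric_b: np.ndarray) -> tuple[float, float]:
    """Classic paired two-tailed t-test on per-fold metric values.

    Returns ``(t, p)`` with p from Student's t on n-1 degrees of freedom.
    Degenerate cases: all differences zero -> (0, 1); constant nonzero
    differences -> p ~ 0 with a degeneracy warning.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D samples with n >= 2")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.allclose(diffs, 0.0):
            return 0.0, 1.0
        warnings.warn("constant nonzero paired differences: p-value degenerate")
        return math.copysign(math.inf, diffs.mean()), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
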