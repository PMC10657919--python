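"""Voxel-level and image-level evaluation with bootstrap confidence intervals.

Voxel metrics (precision, recall, dice at a 0.5 threshold, area under the
precision-recall curve, expected calibration error) pool voxels across all
patches ("micro" averaging), consistent with reporting one dataset-level
value.  Image metrics are accuracy, sensitivity, specificity and the
rank-based AUC.  Confidence intervals come from nonparametric bootstrap
resampling (default 500 replicates) with the 2.5th/97.5th centiles of the
replicate distribution.

Calibration and thresholded overlap metrics require probability-valued
predictions; saliency maps with unbounded scores are evaluated with AUPR
only.

Zero-denominator conventions: precision/recall/dice are 1 when both the
prediction and the truth are empty (a perfect empty match) and 0 when the
denominator vanishes while errors exist.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import DegenerateDataError, UndefinedMetricError

__all__ = [
    "BootstrapConfig",
    "MetricValue",
    "MetricReport",
    "voxel_confusion",
    "precision_recall_dice",
    "aupr",
    "expected_calibration_error",
    "image_metrics",
    "bootstrap_ci",
    "evaluate_voxels",
    "evaluate_images",
]


@dataclass(frozen=True)
class BootstrapConfig:
    n_bootstraps: int = 500
    centiles: Tuple[float, float] = (2.5, 97.5)
    resample_unit: str = "patch"  # 'patch' | 'subject'
    seed: int = 0
    max_retries: int = 100

    def __post_init__(self):
        if self.n_bootstraps < 1:
            raise ValueError("n_bootstraps must be >= 1")
        if self.centiles[0] >= self.centiles[1]:
            raise ValueError("centiles must be ordered")


@dataclass
class MetricValue:
    value: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


@dataclass
class MetricReport:
    """Named metric values with bootstrap CIs and the config that made them."""

    metrics: Dict[str, MetricValue]
    n_bootstraps: int = 0
    resample_unit: str = "patch"
    context: Dict[str, object] = field(default_factory=dict)

    def to_frame(self, partition: str = "", method: str = "") -> pd.DataFrame:
        rows = [
            {"partition": partition, "method": method, "metric": name,
             "value": mv.value, "ci_low": mv.ci_low, "ci_high": mv.ci_high}
            for name, mv in self.metrics.items()
        ]
        return pd.DataFrame(rows)

    def to_json(self, path=None) -> str:
        payload = {
            "metrics": {k: asdict(v) for k, v in self.metrics.items()},
            "n_bootstraps": self.n_bootstraps,
            "resample_unit": self.resample_unit,
            "context": self.context,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def __getitem__(self, name: str) -> MetricValue:
        return self.metrics[name]


# ---------------------------------------------------------------------------
# voxel-level metrics
# ---------------------------------------------------------------------------


def voxel_confusion(predictions: Sequence[np.ndarray], masks: Sequence[np.ndarray],
                    threshold: float = 0.5) -> Tuple[int, int, int, int]:
    """Pooled (tp, fp, fn, tn) over all voxels; positive iff score >= threshold."""
    tp = fp = fn = tn = 0
    for pred, mask in zip(predictions, masks):
        pred, mask = np.asarray(pred), np.asarray(mask)
        if pred.shape != mask.shape:
            raise ValueError(f"shape mismatch {pred.shape} vs {mask.shape}")
        hard = pred >= threshold
        truth = mask > 0
        tp += int(np.sum(hard & truth))
        fp += int(np.sum(hard & ~truth))
        fn += int(np.sum(~hard & truth))
        tn += int(np.sum(~hard & ~truth))
    return tp, fp, fn, tn


def precision_recall_dice(tp: int, fp: int, fn: int) -> Tuple[float, float, float]:
    def ratio(num, den):
        if den == 0:
            return 1.0 if (tp + fp + fn) == 0 else 0.0
        return num / den

    return (
        ratio(tp, tp + fp),
        ratio(tp, tp + fn),
        ratio(2 * tp, 2 * tp + fp + fn),
    )


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve by average-precision summation."""
    scores = np.ravel(scores)
    labels = np.ravel(labels)
    if labels.min(initial=1) == labels.max(initial=0):
        raise UndefinedMetricError("AUPR needs both classes present")
    return float(average_precision_score(labels, scores))


def expected_calibration_error(probabilities: np.ndarray, labels: np.ndarray,
                               n_bins: int = 10) -> float:
    """Bin-weighted mean |empirical positive rate - mean predicted probability|.

    Equal-width bins on [0, 1]; the last bin is closed at 1.
    """
    p = np.ravel(np.asarray(probabilities, dtype=float))
    y = np.ravel(np.asarray(labels, dtype=float))
    if p.size == 0:
        raise ValueError("empty input")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    bins = np.minimum((p * n_bins).astype(int), n_bins - 1)
    ece = 0.0
    for b in range(n_bins):
        sel = bins == b
        nb = int(sel.sum())
        if nb == 0:
            continue
        ece += (nb / p.size) * abs(y[sel].mean() - p[sel].mean())
    return float(ece)


# ---------------------------------------------------------------------------
# image-level metrics
# ---------------------------------------------------------------------------


def image_metrics(scores: np.ndarray, labels: np.ndarray,
                  threshold: float = 0.5) -> Dict[str, float]:
    """Accuracy, sensitivity, specificity at the threshold plus rank AUC.

    AUC is the probability that a random positive outranks a random
    negative (ties count one half); it requires both classes and raises
    :class:`UndefinedMetricError` otherwise while the thresholded metrics
    remain available through the returned dict of a single-class call.
    """
    s = np.ravel(np.asarray(scores, dtype=float))
    y = np.ravel(np.asarray(labels)).astype(int)
    hard = s >= threshold
    pos, neg = y == 1, y == 0
    out = {"accuracy": float((hard == y).mean())}
    out["sensitivity"] = float(hard[pos].mean()) if pos.any() else float("nan")
    out["specificity"] = float((~hard[neg]).mean()) if neg.any() else float("nan")
    if pos.any() and neg.any():
        out["auc"] = float(roc_auc_score(y, s))
    else:
        raise UndefinedMetricError(
            f"AUC needs both classes; thresholded metrics: {out}")
    return out


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_ci(metric_fn: Callable[[np.ndarray], float], n_units: int,
                 config: BootstrapConfig = BootstrapConfig()) -> Tuple[float, float, float]:
    """(point, ci_low, ci_high) for a metric of resampled unit indices.

    ``metric_fn`` receives an integer index array selecting units (patches
    or subjects) with replacement; the point estimate uses the identity
    selection.  Replicates on which the metric is undefined are redrawn up
    to ``max_retries`` times each.
    """
    if n_units < 1:
        raise ValueError("no data to resample")
    rng = np.random.default_rng(config.seed)
    point = metric_fn(np.arange(n_units))
    reps = np.empty(config.n_bootstraps)
    for b in range(config.n_bootstraps):
        for attempt in range(config.max_retries + 1):
            idx = rng.integers(0, n_units, n_units)
            try:
                reps[b] = metric_fn(idx)
                break
            except UndefinedMetricError:
                if attempt == config.max_retries:
                    raise DegenerateDataError(
                        "metric undefined on too many bootstrap replicates")
    lo, hi = np.percentile(reps, config.centiles)
    return float(point), float(lo), float(hi)


# ---------------------------------------------------------------------------
# report-level drivers
# ---------------------------------------------------------------------------


def _unit_groups(subject_ids: Optional[Sequence[str]], n: int, unit: str) -> List[np.ndarray]:
    if unit == "subject":
        if subject_ids is None:
            raise ValueError("subject-level resampling needs subject_ids")
        order: Dict[str, List[int]] = {}
        for i, s in enumerate(subject_ids):
            order.setdefault(s, []).append(i)
        return [np.array(v) for v in order.values()]
    return [np.array([i]) for i in range(n)]


def _expand(groups: List[np.ndarray], gidx: np.ndarray) -> np.ndarray:
    return np.concatenate([groups[g] for g in gidx])


def evaluate_voxels(predictions: np.ndarray, masks: np.ndarray,
                    is_probability: bool = True, threshold: float = 0.5,
                    n_bins: int = 10,
                    bootstrap: Optional[BootstrapConfig] = None,
                    subject_ids: Optional[Sequence[str]] = None) -> MetricReport:
    """Voxel-level report for per-patch score grids against binary masks.

    With ``is_probability=False`` (saliency comparators) only AUPR is
    computed, mirroring the fact that calibration and thresholded overlap
    are undefined for unbounded relevance scores.
    """
    preds = np.asarray(predictions, dtype=float)
    masks = np.asarray(masks)
    if preds.shape != masks.shape:
        raise ValueError("predictions and masks must align")
    n = len(preds)

    def compute(idx: np.ndarray) -> Dict[str, float]:
        p, m = preds[idx], masks[idx]
        out: Dict[str, float] = {"aupr": aupr(p, m)}
        if is_probability:
            tp, fp, fn, _ = voxel_confusion(p, m, threshold)
            out["precision"], out["recall"], out["dice"] = precision_recall_dice(tp, fp, fn)
            out["ece"] = expected_calibration_error(p, m, n_bins)
        return out

    return _report(compute, n, bootstrap, subject_ids,
                   context={"threshold": threshold, "n_bins": n_bins,
                            "is_probability": is_probability})


def evaluate_images(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5,
                    bootstrap: Optional[BootstrapConfig] = None,
                    subject_ids: Optional[Sequence[str]] = None) -> MetricReport:
    """Image-level report (accuracy, sensitivity, specificity, AUC)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)

    def compute(idx: np.ndarray) -> Dict[str, float]:
        return image_metrics(s[idx], y[idx], threshold)

    return _report(compute, len(s), bootstrap, subject_ids,
                   context={"threshold": threshold})


def _report(compute: Callable[[np.ndarray], Dict[str, float]], n: int,
            bootstrap: Optional[BootstrapConfig],
            subject_ids: Optional[Sequence[str]],
            context: Dict[str, object]) -> MetricReport:
    point = compute(np.arange(n))
    report = MetricReport({k: MetricValue(v) for k, v in point.items()},
                          context=context)
    if bootstrap is None:
        return report
    groups = _unit_groups(subject_ids, n, bootstrap.resample_unit)
    rng = np.random.default_rng(bootstrap.seed)
    reps: Dict[str, List[float]] = {k: [] for k in point}
    for _ in range(bootstrap.n_bootstraps):
        for attempt in range(bootstrap.max_retries + 1):
            gidx = rng.integers(0, len(groups), len(groups))
            try:
                rep = compute(_expand(groups, gidx))
                break
            except UndefinedMetricError:
                if attempt == bootstrap.max_retries:
                    raise DegenerateDataError(
                        "metric undefined on too many bootstrap replicates")
        for k, v in rep.items():
            reps[k].append(v)
    for k in point:
        lo, hi = np.percentile(reps[k], bootstrap.centiles)
        report.metrics[k].ci_low = float(lo)
        report.metrics[k].ci_high = float(hi)
    report.n_bootstraps = bootstrap.n_bootstraps
    report.resample_unit = bootstrap.resample_unit
    return report
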