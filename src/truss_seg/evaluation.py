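"""Pixel-level segmentation evaluation.

Metrics follow the residual-ratio convention: overlay prediction and
ground-truth ROI, remove one from the other, and report what remains.

* **FN%** — of the actual ROI's pixels, the fraction the prediction missed:
  ``100 * |truth \\ pred| / |truth|``.
* **FP%** — of the predicted pixels, the fraction outside the actual ROI:
  ``100 * |pred \\ truth| / |pred|``.
* **mIoU%** — ``100 * |pred & truth| / |pred | truth|``.

A metric whose denominator is empty is *undefined* for that image; such
images are excluded from aggregates (and recorded), never imputed.
Aggregates are reported as mean ± sample (n-1) standard deviation.
ROC/AUC sweep a continuous per-pixel score against the truth labels.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn import metrics as skmetrics

__all__ = [
    "UndefinedMetricError",
    "PixelCounts",
    "ImageMetrics",
    "EvalReport",
    "residual_fn",
    "residual_fp",
    "miou",
    "roc_auc",
    "evaluate_dataset",
]


class UndefinedMetricError(ValueError):
    """The metric's denominator is empty for this mask pair."""


@dataclass(frozen=True)
class PixelCounts:
    """Confusion counts for one (prediction, truth) mask pair."""

    tp: int
    fp: int
    fn: int
    tn: int

    @classmethod
    def from_masks(cls, pred: np.ndarray, truth: np.ndarray) -> "PixelCounts":
        pred, truth = _check_pair(pred, truth)
        return cls(
            tp=int((pred & truth).sum()),
            fp=int((pred & ~truth).sum()),
            fn=int((~pred & truth).sum()),
            tn=int((~pred & ~truth).sum()),
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _check_pair(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    return pred, truth


def residual_fn(pred: np.ndarray, truth: np.ndarray) -> float:
    """Percent of the actual ROI remaining after removing predicted pixels."""
    pred, truth = _check_pair(pred, truth)
    n_truth = int(truth.sum())
    if n_truth == 0:
        raise UndefinedMetricError("FN undefined: empty ground-truth ROI")
    return 100.0 * int((truth & ~pred).sum()) / n_truth


def residual_fp(pred: np.ndarray, truth: np.ndarray) -> float:
    """Percent of the predicted ROI remaining after removing actual pixels."""
    pred, truth = _check_pair(pred, truth)
    n_pred = int(pred.sum())
    if n_pred == 0:
        raise UndefinedMetricError("FP undefined: empty prediction")
    return 100.0 * int((pred & ~truth).sum()) / n_pred


def miou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Percent intersection-over-union of the two masks."""
    pred, truth = _check_pair(pred, truth)
    union = int((pred | truth).sum())
    if union == 0:
        raise UndefinedMetricError("IoU undefined: both masks empty")
    return 100.0 * int((pred & truth).sum()) / union


def roc_auc(
    scores: np.ndarray, truth: np.ndarray
) -> tuple[np.ndarray, float]:
    """Threshold sweep of a per-pixel score against boolean truth.

    Returns ``(points, auc)`` where ``points`` is an ``(n, 2)`` array of
    (false-positive rate, true-positive rate) ordered by increasing FPR
    and ``auc`` is the trapezoidal area under that curve.  AUC 0.5 is the
    chance diagonal; constant scores land exactly there.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    truth = np.asarray(truth, dtype=bool).ravel()
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have the same number of pixels")
    if truth.all() or not truth.any():
        raise ValueError("ROC requires both classes present in truth")
    fpr, tpr, _ = skmetrics.roc_curve(truth.astype(int), scores)
    points = np.column_stack([fpr, tpr])
    return points, float(skmetrics.auc(fpr, tpr))


@dataclass
class ImageMetrics:
    """Per-image metric row; ``None`` marks an undefined metric."""

    id: str
    fn_pct: float | None
    fp_pct: float | None
    miou_pct: float | None


def _agg(values: list[float]) -> dict:
    if not values:
        return {"mean": None, "sd": None, "n": 0}
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return {"mean": mean, "sd": sd, "n": len(values)}


@dataclass
class EvalReport:
    """Per-image metrics plus aggregates, ROC points and AUC."""

    per_image: list[ImageMetrics]
    aggregate: dict  # metric -> {mean, sd, n}
    excluded: dict  # metric -> [image ids where undefined]
    roc: np.ndarray | None = None  # (n, 2) fpr, tpr
    auc: float | None = None
    degenerate_sd: bool = False  # single-image sample: sd reported as 0

    def summary_lines(self) -> list[str]:
        lines = []
        for metric in ("fn_pct", "fp_pct", "miou_pct"):
            agg = self.aggregate[metric]
            if agg["n"] == 0:
                lines.append(f"{metric}: undefined (no valid images)")
            else:
                lines.append(
                    f"{metric}: {agg['mean']:.2f} ± {agg['sd']:.2f} % "
                    f"(n={agg['n']})"
                )
        if self.auc is not None:
            lines.append(f"auc: {self.auc:.3f}")
        return lines

    def to_json(self) -> str:
        payload = {
            "per_image": [
                {"id": m.id, "fn_pct": m.fn_pct, "fp_pct": m.fp_pct, "miou_pct": m.miou_pct}
                for m in self.per_image
            ],
            "aggregate": self.aggregate,
            "excluded": self.excluded,
            "roc": None if self.roc is None else self.roc.tolist(),
            "auc": self.auc,
            "degenerate_sd": self.degenerate_sd,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        d = json.loads(text)
        return cls(
            per_image=[ImageMetrics(**m) for m in d["per_image"]],
            aggregate=d["aggregate"],
            excluded=d["excluded"],
            roc=None if d["roc"] is None else np.asarray(d["roc"], dtype=np.float64),
            auc=d["auc"],
            degenerate_sd=d["degenerate_sd"],
        )

    def write(self, out_dir: str | Path, stem: str = "metrics") -> None:
        """CSV of per-image rows, JSON summary, ROC points CSV."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / f"{stem}.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "fn_pct", "fp_pct", "miou_pct"])
            for m in self.per_image:
                w.writerow([m.id, m.fn_pct, m.fp_pct, m.miou_pct])
        (out_dir / f"{stem}.json").write_text(self.to_json())
        if self.roc is not None:
            with open(out_dir / f"{stem}_roc.csv", "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["fpr", "tpr"])
                w.writerows(self.roc.tolist())


def evaluate_dataset(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    ids: list[str] | None = None,
    scores: list[np.ndarray] | None = None,
) -> EvalReport:
    """Evaluate (prediction, truth) mask pairs; optionally pooled ROC.

    ``scores``, when given, must parallel ``pairs``; ROC/AUC are computed
    over the pooled pixels of all images.  Images where a metric is
    undefined (empty denominator) are excluded from that metric's
    aggregate and listed in ``report.excluded``.
    """
    if not pairs:
        raise ValueError("need at least one (pred, truth) pair")
    if ids is None:
        ids = [f"img_{i:04d}" for i in range(len(pairs))]
    per_image: list[ImageMetrics] = []
    excluded: dict[str, list[str]] = {"fn_pct": [], "fp_pct": [], "miou_pct": []}
    collected: dict[str, list[float]] = {"fn_pct": [], "fp_pct": [], "miou_pct": []}
    for sid, (pred, truth) in zip(ids, pairs):
        row = {}
        for name, fn in (
            ("fn_pct", residual_fn),
            ("fp_pct", residual_fp),
            ("miou_pct", miou),
        ):
            try:
                val = fn(pred, truth)
                collected[name].append(val)
            except UndefinedMetricError:
                val = None
                excluded[name].append(sid)
            row[name] = val
        per_image.append(ImageMetrics(id=sid, **row))

    aggregate = {k: _agg(v) for k, v in collected.items()}
    roc = auc = None
    if scores is not None:
        if len(scores) != len(pairs):
            raise ValueError("scores must parallel pairs")
        pooled_s = np.concatenate([np.ravel(s) for s in scores])
        pooled_t = np.concatenate([np.ravel(t) for _, t in pairs]).astype(bool)
        if pooled_t.any() and not pooled_t.all():
            roc, auc = roc_auc(pooled_s, pooled_t)
    return EvalReport(
        per_image=per_image,
        aggregate=aggregate,
        excluded=excluded,
        roc=roc,
        auc=auc,
        degenerate_sd=(len(pairs) == 1),
    )
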