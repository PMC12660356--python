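"""Classification metrics, cross-validation, explainability and statistics.

The positive class throughout is "infected".  Metric percentages are
reported unrounded; :func:`round_table` applies the one-decimal
round-half-up convention used in report tables.  Ratios with zero
denominators are reported as ``None`` (a flagged null), never 0.

Explainability follows the Grad-CAM protocol: the gradient of the
predicted-class score with respect to a chosen feature layer weights
that layer's channels; the rectified weighted sum, upsampled and
max-normalized, is the heatmap.  Heatmaps are scored against
ground-truth follicle masks with IoU, Dice, pointing-game accuracy and
the energy-based localization score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import KFold
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from .model import FCAUNet
from .nn.engine import Tensor

__all__ = [
    "ConfusionMatrix",
    "PairedTestResult",
    "FoldPlan",
    "confusion",
    "classification_metrics",
    "roc_pr",
    "kfold_split",
    "aggregate_folds",
    "round_half_up",
    "round_table",
    "grad_cam",
    "heatmap_region",
    "iou",
    "dsc",
    "pointing_game",
    "energy_score",
    "paired_t_test",
    "mcnemar",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with "infected" as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionMatrix:
    """Confusion counts from 0/1 labels and predictions (1 = infected)."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.size == 0:
        raise ValueError("cannot build a confusion matrix from no samples")
    if y.shape != p.shape:
        raise ValueError("labels and predictions differ in length")
    return ConfusionMatrix(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
        tn=int(np.sum((y == 0) & (p == 0))),
    )


def _ratio(num: float, den: float) -> Optional[float]:
    return None if den == 0 else 100.0 * num / den


def classification_metrics(cm: ConfusionMatrix) -> dict[str, Optional[float]]:
    """Accuracy, precision, recall, specificity and F1 as percentages."""
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": _ratio(cm.tp + cm.tn, cm.total),
        "precision": precision,
        "recall": recall,
        "specificity": _ratio(cm.tn, cm.tn + cm.fp),
        "f1": f1,
    }


def roc_pr(labels: Sequence[int], scores: Sequence[float]) -> dict:
    """ROC and PR curves with trapezoidal areas (positive class 1)."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    fpr, tpr, _ = roc_curve(y, s)
    prec, rec, _ = precision_recall_curve(y, s)
    return {
        "roc": {"fpr": fpr, "tpr": tpr, "auc": float(sk_auc(fpr, tpr))},
        "pr": {"precision": prec, "recall": rec,
               "auc": float(sk_auc(rec, prec))},
    }


@dataclass(frozen=True)
class FoldPlan:
    k: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("need at least 2 folds")


def kfold_split(n_samples: int, plan: FoldPlan = FoldPlan()) -> list[np.ndarray]:
    """Disjoint shuffled folds covering every index, sizes within 1."""
    if n_samples < plan.k:
        raise ValueError("fewer samples than folds")
    kf = KFold(n_splits=plan.k, shuffle=True, random_state=plan.seed)
    return [test for _, test in kf.split(np.arange(n_samples))]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Report-table rounding (0.05 -> 0.1 at one decimal)."""
    factor = 10 ** decimals
    return math.floor(x * factor + 0.5) / factor


def aggregate_folds(per_fold: Sequence[dict]) -> dict[str, float]:
    """Arithmetic mean of each metric across folds (unrounded)."""
    if not per_fold:
        raise ValueError("no folds to aggregate")
    keys = per_fold[0].keys()
    if any(t.keys() != keys for t in per_fold):
        raise ValueError("fold tables disagree on metric names")
    return {k: float(np.mean([t[k] for t in per_fold])) for k in keys}


def round_table(table: dict[str, float], decimals: int = 1) -> dict[str, float]:
    return {k: round_half_up(v, decimals) for k, v in table.items()}


# ---------------------------------------------------------------------
# explainability
# ---------------------------------------------------------------------


def grad_cam(model: FCAUNet, image: np.ndarray,
             layer_selector: str = "last_decoder") -> np.ndarray:
    """Gradient-weighted class activation heatmap in [0, 1].

    ``layer_selector`` names a recorded activation ("encoder0"...,
    "bottleneck", "decoder0"..., or "last_decoder" for the final
    decoder convolution).  The gradient of the predicted-class logit is
    pooled per channel, the rectified weighted channel sum is
    upsampled to the image grid and normalized by its maximum; an
    all-zero gradient yields an all-zero heatmap.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("grad_cam expects a single 2-D image")
    x = (img / 255.0)[None, None]
    model.eval()
    logits, _ = model(Tensor(x))
    if layer_selector == "last_decoder":
        layer_selector = f"decoder{len(model.decoders) - 1}"
    if layer_selector not in model.activations:
        raise KeyError(
            f"unknown layer {layer_selector!r}; available: "
            f"{sorted(model.activations)}"
        )
    act = model.activations[layer_selector]
    cls = int(np.argmax(logits.data[0]))
    seed_grad = np.zeros_like(logits.data)
    seed_grad[0, cls] = 1.0
    logits.backward(seed_grad)
    if act.grad is None:
        return np.zeros_like(img)
    weights = act.grad[0].mean(axis=(1, 2))  # GAP of d(score)/d(activation)
    cam = np.maximum((weights[:, None, None] * act.data[0]).sum(axis=0), 0.0)
    if cam.shape != img.shape:
        zy = img.shape[0] / cam.shape[0]
        zx = img.shape[1] / cam.shape[1]
        from scipy.ndimage import zoom
        cam = zoom(cam, (zy, zx), order=1)
        cam = cam[:img.shape[0], :img.shape[1]]
    peak = cam.max()
    return cam / peak if peak > 0 else cam


def heatmap_region(heatmap: np.ndarray, keep_fraction: float = 0.2) -> np.ndarray:
    """Binary region of the top ``keep_fraction`` most-activated pixels."""
    h = np.asarray(heatmap, dtype=np.float64)
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must lie in (0, 1]")
    thr = np.quantile(h, 1.0 - keep_fraction)
    return (h >= thr).astype(np.uint8)


def _binary(a) -> np.ndarray:
    a = np.asarray(a)
    return (a > 0).astype(np.int64)


def iou(p: np.ndarray, g: np.ndarray) -> float:
    """|P∩G| / |P∪G|; defined as 1 when both regions are empty."""
    p, g = _binary(p), _binary(g)
    if p.shape != g.shape:
        raise ValueError("region shapes differ")
    union = int(np.sum(p | g))
    if union == 0:
        return 1.0
    return float(np.sum(p & g)) / union


def dsc(p: np.ndarray, g: np.ndarray) -> float:
    """Dice coefficient 2|P∩G| / (|P|+|G|); 1 when both regions are empty."""
    p, g = _binary(p), _binary(g)
    if p.shape != g.shape:
        raise ValueError("region shapes differ")
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * float(np.sum(p & g)) / denom


def pointing_game(pairs: Sequence[tuple[np.ndarray, np.ndarray]]) -> float:
    """Percentage of heatmaps whose peak pixel lies in the truth region.

    Argmax ties break toward the first pixel in row-major order.
    """
    if not pairs:
        raise ValueError("pointing game needs at least one pair")
    hits = 0
    for heatmap, g in pairs:
        h = np.asarray(heatmap, dtype=np.float64)
        g = _binary(g)
        r, c = np.unravel_index(int(np.argmax(h)), h.shape)
        hits += int(g[r, c] == 1)
    return 100.0 * hits / len(pairs)


def energy_score(heatmap: np.ndarray, g: np.ndarray) -> Optional[float]:
    """Percent of heatmap energy inside the truth region; None if no energy."""
    h = np.asarray(heatmap, dtype=np.float64)
    g = _binary(g)
    if h.shape != g.shape:
        raise ValueError("shapes differ")
    total = float(h.sum())
    if total == 0.0:
        return None
    return 100.0 * float(h[g == 1].sum()) / total


# ---------------------------------------------------------------------
# statistical tests
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class PairedTestResult:
    diffs: tuple[float, ...]
    mean_diff: float
    variance: float
    sd: float
    t_value: float
    dof: int
    p_value: float
    ci_low: float
    ci_high: float
    flag: Optional[str] = None


def paired_t_test(acc_a: Sequence[float], acc_b: Sequence[float],
                  confidence: float = 0.95) -> PairedTestResult:
    """Paired t-test on per-run accuracy differences (b - a).

    Sample variance uses the n-1 denominator; the two-sided p-value
    comes from the t distribution with n-1 degrees of freedom and the
    confidence interval is ``mean ± t_crit * SD / sqrt(n)``.  A zero
    SD yields an infinite t (flagged), with p = 0 unless the mean
    difference is also zero (then t = 0, p = 1).
    """
    a = np.asarray(acc_a, dtype=np.float64)
    b = np.asarray(acc_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1-D accuracy vectors")
    n = a.size
    if n < 2:
        raise ValueError("need at least two paired runs")
    diffs = b - a
    mean = float(diffs.mean())
    var = float(diffs.var(ddof=1))
    sd = math.sqrt(var)
    dof = n - 1
    tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, dof))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(tuple(diffs), mean, var, sd, 0.0, dof, 1.0,
                                    mean, mean, flag="zero variance, zero mean")
        t_val = math.inf if mean > 0 else -math.inf
        return PairedTestResult(tuple(diffs), mean, var, sd, t_val, dof, 0.0,
                                mean, mean, flag="zero variance")
    se = sd / math.sqrt(n)
    t_val = mean / se
    p = 2.0 * float(stats.t.sf(abs(t_val), dof))
    return PairedTestResult(tuple(diffs), mean, var, sd, t_val, dof, p,
                            mean - tcrit * se, mean + tcrit * se)


def mcnemar(preds_a: Sequence[int], preds_b: Sequence[int],
            labels: Sequence[int], exact_threshold: int = 25) -> dict:
    """McNemar test on the discordant pairs of two classifiers.

    The statistic is the continuity-corrected chi-square
    ``(|b - c| - 1)^2 / (b + c)`` on the discordant counts; the
    p-value falls back to the exact binomial test when the discordant
    total is below ``exact_threshold``.  Identical predictions give
    statistic 0 and p = 1.
    """
    pa = np.asarray(preds_a)
    pb = np.asarray(preds_b)
    y = np.asarray(labels)
    if not (pa.shape == pb.shape == y.shape):
        raise ValueError("prediction/label lengths differ")
    a_right = pa == y
    b_right = pb == y
    n01 = int(np.sum(a_right & ~b_right))   # a correct, b wrong
    n10 = int(np.sum(~a_right & b_right))   # a wrong, b correct
    disc = n01 + n10
    if disc == 0:
        return {"statistic": 0.0, "p_value": 1.0, "discordant": (n01, n10),
                "method": "degenerate"}
    statistic = (abs(n01 - n10) - 1) ** 2 / disc
    table = [[0, n01], [n10, 0]]
    if disc < exact_threshold:
        res = sm_mcnemar(table, exact=True)
        return {"statistic": float(statistic), "p_value": float(res.pvalue),
                "discordant": (n01, n10), "method": "exact-binomial"}
    res = sm_mcnemar(table, exact=False, correction=True)
    return {"statistic": float(statistic), "p_value": float(res.pvalue),
            "discordant": (n01, n10), "method": "chi2-corrected"}
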