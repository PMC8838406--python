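"""Segmentation quality metrics: Acc/Se/Sp, SSIM, and S-measure.

Pixel-count metrics come from the confusion counts of a binary
prediction against binary ground truth, optionally restricted to a
field-of-view mask:

    Acc = (TP + TN) / total,  Se = TP / (TP + FN),  Sp = TN / (TN + FP).

Because those treat pixels as independent, two structure-aware
complements are provided: SSIM (local luminance/contrast/structure
comparison with the reference 11x11 Gaussian window) and the S-measure,
which scores a foreground map against binary truth as a convex mix of an
object-aware term (foreground and background similarity) and a
region-aware term (per-quadrant structural comparison about the truth
centroid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .errors import ParameterError, ShapeError

_EPS = np.finfo(float).eps


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.total


@dataclass(frozen=True)
class MetricsReport:
    acc: float | None
    se: float | None
    sp: float | None
    ssim: float | None = None
    s_measure: float | None = None


def _check_same_shape(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ShapeError(f"shapes differ: {sorted(shapes)}")


def confusion(
    pred: np.ndarray, truth: np.ndarray, fov: np.ndarray | None = None
) -> ConfusionCounts:
    """TP/FP/TN/FN over FOV pixels (all pixels when no FOV is given)."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if fov is not None:
        fov = np.asarray(fov).astype(bool)
        _check_same_shape(pred, truth, fov)
        pred, truth = pred[fov], truth[fov]
    else:
        _check_same_shape(pred, truth)
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def acc_se_sp(
    c: ConfusionCounts,
) -> tuple[float | None, float | None, float | None]:
    """Accuracy, sensitivity, specificity; ``None`` where the denominator is 0."""
    if c.total == 0:
        raise ParameterError("confusion counts are empty")
    acc = (c.tp + c.tn) / c.total
    se = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    return acc, se, sp


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Mean local SSIM with the reference defaults.

    11x11 Gaussian window (sigma 1.5), stabilizers C1 = (0.01 R)^2 and
    C2 = (0.03 R)^2 for dynamic range R = 1 (images are in [0, 1]).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_same_shape(a, b)
    return float(
        structural_similarity(
            a, b, win_size=11, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, data_range=1.0,
        )
    )


def _object_score(values: np.ndarray) -> float:
    """Similarity of a response distribution to the ideal constant 1."""
    if values.size == 0:
        return 0.0
    x = float(values.mean())
    sigma_x = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return 2.0 * x / (x * x + 1.0 + sigma_x + _EPS)


def _s_object(pred: np.ndarray, truth: np.ndarray) -> float:
    o_fg = _object_score(pred[truth])
    o_bg = _object_score(1.0 - pred[~truth])
    u = float(truth.mean())
    return u * o_fg + (1.0 - u) * o_bg


def _structure_q(x: np.ndarray, y: np.ndarray) -> float:
    """SSIM-form similarity of one region, from global region statistics."""
    n = x.size
    if n <= 1:
        return 1.0
    mx, my = float(x.mean()), float(y.mean())
    vx = float(x.var(ddof=1))
    vy = float(y.var(ddof=1))
    cxy = float(((x - mx) * (y - my)).sum() / (n - 1))
    alpha = 4.0 * mx * my * cxy
    beta = (mx * mx + my * my) * (vx + vy)
    if alpha != 0.0:
        return alpha / (beta + _EPS)
    return 1.0 if beta == 0.0 else 0.0


def _s_region(pred: np.ndarray, truth: np.ndarray) -> float:
    rows, cols = np.nonzero(truth)
    # centroid of the truth foreground, used as the quadrant split point
    cr = int(np.round(rows.mean())) + 1
    cc = int(np.round(cols.mean())) + 1
    h, w = truth.shape
    total = h * w
    score = 0.0
    for rs, cs in ((slice(0, cr), slice(0, cc)),
                   (slice(0, cr), slice(cc, w)),
                   (slice(cr, h), slice(0, cc)),
                   (slice(cr, h), slice(cc, w))):
        t_q = truth[rs, cs]
        weight = t_q.size / total
        score += weight * _structure_q(
            pred[rs, cs].astype(float), t_q.astype(float)
        )
    return score


def s_measure(pred: np.ndarray, truth: np.ndarray, alpha: float = 0.5) -> float:
    """Structure measure of a [0,1] foreground map against binary truth.

    S = alpha * S_object + (1 - alpha) * S_region.  Degenerate truths
    fall back to mean-intensity agreement: all-background truth scores
    ``1 - mean(pred)``, all-foreground truth scores ``mean(pred)``.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth).astype(bool)
    _check_same_shape(pred, truth)
    if pred.min() < -1e-9 or pred.max() > 1.0 + 1e-9:
        raise ParameterError("prediction map must lie in [0, 1]")
    u = float(truth.mean())
    if u == 0.0:
        return 1.0 - float(pred.mean())
    if u == 1.0:
        return float(pred.mean())
    s = alpha * _s_object(pred, truth) + (1.0 - alpha) * _s_region(pred, truth)
    return float(max(0.0, min(1.0, s)))


def report(
    pred: np.ndarray,
    truth: np.ndarray,
    fov: np.ndarray | None = None,
) -> MetricsReport:
    """All five metrics of a binary prediction against binary truth.

    SSIM and S-measure are computed on the full maps with out-of-FOV
    pixels zeroed on both sides, matching the count metrics' FOV
    restriction.
    """
    pred_b = np.asarray(pred).astype(bool)
    truth_b = np.asarray(truth).astype(bool)
    if fov is not None:
        fov_b = np.asarray(fov).astype(bool)
        pred_m, truth_m = pred_b & fov_b, truth_b & fov_b
    else:
        pred_m, truth_m = pred_b, truth_b
    acc, se, sp = acc_se_sp(confusion(pred_b, truth_b, fov))
    return MetricsReport(
        acc=acc,
        se=se,
        sp=sp,
        ssim=ssim(pred_m.astype(float), truth_m.astype(float)),
        s_measure=s_measure(pred_m.astype(float), truth_m),
    )
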