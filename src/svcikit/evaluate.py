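"""Classification metrics, curves, AUC comparison, CIs, and relevance checks.

Point metrics (accuracy, recall, specificity, F1) are computed in exact
rational arithmetic from the confusion matrix with SVCI as the positive
class.  AUC is the trapezoidal area under the ROC built over all score
thresholds (equal scores grouped into one step), which equals the
Mann-Whitney U statistic divided by ``n_pos * n_neg``.  Confidence intervals
are Clopper-Pearson exact for proportion-type metrics and percentile
bootstrap (2000 resamples) for F1.  Paired AUCs are compared with the DeLong
structural-components test.

The F1 contract is the binary positive-class definition
``2 TP / (2 TP + FP + FN)``; a support-weighted average of the two per-class
F1 values is available as a secondary option.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .io import SCALE_SIGNS

__all__ = [
    "ConfusionMatrix",
    "confusion_from_predictions",
    "metrics_from_confusion",
    "clopper_pearson",
    "bootstrap_f1_ci",
    "auc_trapezoid",
    "calibration_curve",
    "decision_curve",
    "delong_test",
    "probability_score_correlation",
    "regression_relevance",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_from_predictions(
    labels: np.ndarray, probabilities: np.ndarray, threshold: float = 0.5
) -> ConfusionMatrix:
    """Confusion counts at a probability threshold; exactly 0.5 predicts the
    negative (SIVD) class — the conservative tie-break."""
    y = np.asarray(labels).astype(int)
    pred = (np.asarray(probabilities) > threshold).astype(int)
    return ConfusionMatrix(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
    )


def metrics_from_confusion(cm: ConfusionMatrix, f1_average: str = "binary") -> dict:
    """Accuracy, recall, specificity, and F1 with Clopper-Pearson 95% CIs.

    Metrics whose denominator is empty (no positives or no negatives) are
    returned as ``None`` and flagged.
    """
    out: dict = {"flags": []}

    def frac(num: int, den: int) -> float | None:
        return float(Fraction(num, den)) if den else None

    out["accuracy"] = frac(cm.tp + cm.tn, cm.total)
    out["accuracy_ci"] = clopper_pearson(cm.tp + cm.tn, cm.total)
    out["recall"] = frac(cm.tp, cm.tp + cm.fn)
    out["specificity"] = frac(cm.tn, cm.tn + cm.fp)
    if out["recall"] is None:
        out["flags"].append("no positive subjects: recall undefined")
        out["recall_ci"] = None
    else:
        out["recall_ci"] = clopper_pearson(cm.tp, cm.tp + cm.fn)
    if out["specificity"] is None:
        out["flags"].append("no negative subjects: specificity undefined")
        out["specificity_ci"] = None
    else:
        out["specificity_ci"] = clopper_pearson(cm.tn, cm.tn + cm.fp)
    if f1_average == "binary":
        out["f1"] = frac(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn)
    elif f1_average == "weighted":
        f1_pos = Fraction(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn)
        f1_neg = Fraction(2 * cm.tn, 2 * cm.tn + cm.fn + cm.fp)
        n_pos, n_neg = cm.tp + cm.fn, cm.tn + cm.fp
        out["f1"] = float((f1_pos * n_pos + f1_neg * n_neg) / (n_pos + n_neg))
    else:
        raise ValueError("f1_average must be 'binary' or 'weighted'")
    return out


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Binomial exact (Clopper-Pearson) two-sided confidence interval."""
    if n == 0:
        raise ValueError("zero denominator")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def bootstrap_f1_ci(
    labels: np.ndarray,
    probabilities: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    threshold: float = 0.5,
) -> tuple[float, float, float]:
    """Percentile-bootstrap F1: (median, 2.5th, 97.5th percentile)."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities)
    rng = np.random.default_rng(seed)
    n = len(y)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        yb, pb = y[idx], p[idx]
        pred = (pb > threshold).astype(int)
        tp = int(((pred == 1) & (yb == 1)).sum())
        fp = int(((pred == 1) & (yb == 0)).sum())
        fn = int(((pred == 0) & (yb == 1)).sum())
        den = 2 * tp + fp + fn
        if den:
            vals.append(2 * tp / den)
    q = np.percentile(vals, [50, 2.5, 97.5])
    return float(q[0]), float(q[1]), float(q[2])


def auc_trapezoid(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Trapezoidal AUC with the ROC points (FPR, TPR) over all thresholds."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with a single class")
    order = np.argsort(-s, kind="stable")
    y_sorted, s_sorted = y[order], s[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # group tied scores into one threshold step
    last = np.nonzero(np.diff(s_sorted))[0]
    keep = np.r_[last, len(s_sorted) - 1]
    tpr = np.r_[0.0, tps[keep] / n_pos]
    fpr = np.r_[0.0, fps[keep] / n_neg]
    auc = float(np.sum(np.diff(fpr) * (tpr[1:] + tpr[:-1]) / 2.0))
    return auc, fpr, tpr


def calibration_curve(
    probabilities: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Equal-width reliability table: mean predicted probability vs observed
    SVCI fraction per bin; empty bins omitted."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        rows.append(
            {
                "bin": b,
                "mean_predicted": float(p[sel].mean()),
                "observed_fraction": float(y[sel].mean()),
                "n": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def decision_curve(
    probabilities: np.ndarray,
    labels: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Decision-curve net benefit NB(t) = TP/N - (FP/N) * t/(1-t), with
    treat-all and treat-none references, over a threshold grid in (0, 1)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = np.arange(0.01, 0.995, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.min() <= 0 or thresholds.max() >= 1:
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    prevalence = y.mean()
    rows = []
    for t in thresholds:
        pred = p >= t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        odds = t / (1.0 - t)
        rows.append(
            {
                "threshold": float(t),
                "net_benefit": tp / n - fp / n * odds,
                "treat_all": prevalence - (1 - prevalence) * odds,
                "treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Two-sided DeLong test for paired AUCs; returns (z, p).

    Identical score vectors give z = 0, p = 1 by convention.
    """
    y = np.asarray(labels).astype(int)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if np.array_equal(a, b):
        return 0.0, 1.0
    pos, neg = y == 1, y == 0
    m, n = int(pos.sum()), int(neg.sum())
    if m == 0 or n == 0:
        raise ValueError("both classes required")
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for k, s in enumerate((a, b)):
        x, yneg = s[pos], s[neg]
        rank_all = _midranks(np.r_[x, yneg])
        rank_pos = _midranks(x)
        rank_neg = _midranks(yneg)
        auc = (rank_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        aucs[k] = auc
        v10[k] = (rank_all[:m] - rank_pos) / n
        v01[k] = 1.0 - (rank_all[m:] - rank_neg) / m
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    var = s10[0, 0] / m + s10[1, 1] / m - 2 * s10[0, 1] / m
    var += s01[0, 0] / n + s01[1, 1] / n - 2 * s01[0, 1] / n
    if var <= 0:
        return 0.0, 1.0
    z = (aucs[0] - aucs[1]) / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def probability_score_correlation(
    probabilities: np.ndarray, scores: pd.DataFrame, normality_alpha: float = 0.05
) -> pd.DataFrame:
    """Correlation between predicted SVCI probability and each scale.

    Pearson when both variables pass Shapiro-Wilk normality at
    ``normality_alpha``, Spearman otherwise.  Expected signs follow each
    scale's convention: negative for scales where higher is better
    (MMSE/MoCA/Recalls), positive for timed tests (TMT-A/B).
    """
    p = np.asarray(probabilities, dtype=float)
    if p.std() == 0:
        raise ValueError("constant probability vector")
    p_normal = stats.shapiro(p).pvalue > normality_alpha
    rows = []
    for scale in scores.columns:
        v = scores[scale].to_numpy(dtype=float)
        if v.std() == 0:
            raise ValueError(f"constant score vector for {scale}")
        use_pearson = p_normal and stats.shapiro(v).pvalue > normality_alpha
        if use_pearson:
            r, pval = stats.pearsonr(p, v)
        else:
            res = stats.spearmanr(p, v)
            r, pval = res.statistic, res.pvalue
        rows.append(
            {
                "scale": scale,
                "r": float(r),
                "p": float(pval),
                "method": "pearson" if use_pearson else "spearman",
                "expected_sign": -SCALE_SIGNS.get(scale, 0),
            }
        )
    return pd.DataFrame(rows)


def regression_relevance(
    volumes: np.ndarray,
    region_mask: np.ndarray,
    scores: pd.DataFrame,
    seed: int = 0,
    test_fraction: float = 0.2,
    epochs: int = 30,
    lr: float = 1e-3,
    filters: int = 8,
) -> pd.DataFrame:
    """Neuropsychological relevance of a region via small CNN regression.

    Volumes are zeroed outside ``region_mask`` (salient / non-salient /
    whole-WM comparison masks), a compact 3-stage convolutional regressor is
    trained per scale on 80% of subjects with squared-error loss, and the
    test-set correlation between estimated and true scores is reported.
    """
    from . import nn  # local import keeps module load light

    if not region_mask.any():
        raise ValueError("empty region mask")
    x = np.asarray(volumes, dtype=np.float32) * region_mask[None, None].astype(
        np.float32
    )
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    test_idx, train_idx = order[:n_test], order[n_test:]
    rows = []
    for si, scale in enumerate(scores.columns):
        y = scores[scale].to_numpy(dtype=np.float64)
        mu, sd = y[train_idx].mean(), y[train_idx].std()
        if sd == 0:
            raise ValueError(f"constant scores for {scale}")
        yz = (y - mu) / sd
        model_rng = np.random.default_rng(seed + 1000 + si)
        c_in = x.shape[1]
        layers = []
        c = c_in
        for _ in range(3):
            layers += [
                nn.Conv3d(c, filters, kernel=3, rng=model_rng),
                nn.ReLU(),
                nn.AvgPool3d(),
            ]
            c = filters
        layers.append(nn.GlobalAvgPool())
        net = nn.Sequential(*layers)
        head = nn.Linear(filters, 1, rng=model_rng)
        params = net.parameters() + head.parameters()
        opt = nn.Adam(params, lr=lr, weight_decay=1e-4)
        bs = 8
        for epoch in range(epochs):
            perm = model_rng.permutation(len(train_idx))
            for s0 in range(0, len(train_idx), bs):
                sel = train_idx[perm[s0 : s0 + bs]]
                opt.zero_grad()
                feats = net.forward(
                    np.moveaxis(x[sel], 1, -1), train=True
                )
                pred = head.forward(feats, train=True)[:, 0]
                err = pred - yz[sel]
                g = (2.0 * err / len(sel)).astype(np.float32)[:, None]
                net.backward(head.backward(g))
                opt.step()
        feats = net.forward(np.moveaxis(x[test_idx], 1, -1), train=False)
        pred = head.forward(feats, train=False)[:, 0]
        truth = yz[test_idx]
        if pred.std() == 0 or truth.std() == 0:
            r, pval = 0.0, 1.0
        else:
            r, pval = stats.pearsonr(pred, truth)
        rows.append(
            {"scale": scale, "r": float(r), "p": float(pval), "n_test": len(test_idx)}
        )
    return pd.DataFrame(rows)
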