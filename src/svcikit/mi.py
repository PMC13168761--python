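"""Voxel-wise mutual information between diffusion maps and cognitive scores.

At each in-mask voxel, the MI (in bits) between the voxel's intensity across
subjects and a neuropsychological score vector is estimated from the joint
histogram after equal-width discretization of each variable over its observed
range (default 8 bins).  For multi-channel combinations the per-channel MI is
averaged.  Significance is assessed by permuting scores across subjects
(p = (1 + #{perm MI >= observed}) / (1 + n_perm)), followed by a
Gaussian-random-field family-wise correction of the p-to-z converted map.

Map-to-map similarity uses four metrics: Dice and Jaccard on binarized maps,
a global structural similarity index (SSIM) on min-max normalized maps with
C1 = (0.01 L)^2, C2 = (0.03 L)^2, L = 1, and the Jensen-Shannon divergence
(base-2 logarithm, bounded by 1) of sum-normalized maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .saliency import grf_correct

__all__ = [
    "MapSimilarity",
    "voxelwise_mi",
    "permutation_pvalues",
    "mi_significance",
    "dice_jaccard",
    "global_ssim",
    "js_divergence",
    "map_similarity",
    "pairwise_scale_similarity",
]


def _bin_equal_width(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-width bin indices over the observed range (1-D)."""
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("constant vector cannot be discretized")
    idx = ((x - lo) / (hi - lo) * bins).astype(np.int64)
    return np.minimum(idx, bins - 1)


def _mi_from_joint(counts: np.ndarray) -> np.ndarray:
    """MI in bits from joint count arrays of shape (..., B, B)."""
    n = counts.sum(axis=(-2, -1), keepdims=True)
    pxy = counts / n
    px = pxy.sum(axis=-1, keepdims=True)
    py = pxy.sum(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = pxy * np.log2(pxy / (px * py))
    return np.nansum(term, axis=(-2, -1))


def _voxel_matrix(batch: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Channel-stacked in-mask voxel values, shape (C, N, V)."""
    if batch.ndim == 4:
        batch = batch[:, None]
    return np.stack([batch[:, c][:, mask] for c in range(batch.shape[1])])


def _mi_values(
    vals: np.ndarray, score_bins: np.ndarray, bins: int
) -> np.ndarray:
    """Mean-over-channel MI per voxel; ``vals`` has shape (C, N, V)."""
    c, n, v = vals.shape
    out = np.zeros(v)
    for ch in range(c):
        x = vals[ch]
        lo = x.min(axis=0)
        hi = x.max(axis=0)
        rng = hi - lo
        ok = rng > 0
        vbin = np.zeros_like(x, dtype=np.int64)
        vbin[:, ok] = np.minimum(
            ((x[:, ok] - lo[ok]) / rng[ok] * bins).astype(np.int64), bins - 1
        )
        idx = (
            np.arange(v, dtype=np.int64)[None, :] * bins * bins
            + vbin * bins
            + score_bins[:, None]
        )
        counts = np.bincount(idx.ravel(), minlength=v * bins * bins).reshape(
            v, bins, bins
        )
        mi = _mi_from_joint(counts.astype(np.float64))
        mi[~ok] = 0.0  # constant voxel carries no information
        out += mi
    return out / c


def voxelwise_mi(
    batch: np.ndarray,
    scores: np.ndarray,
    mask: np.ndarray,
    bins: int = 8,
) -> np.ndarray:
    """MI map (bits) between voxel intensities and a score vector.

    ``batch`` is ``(N, C, X, Y, Z)`` (or ``(N, X, Y, Z)`` for one channel);
    returns a volume that is zero outside ``mask``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if batch.shape[0] < 10:
        raise ValueError("need at least 10 subjects for MI estimation")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores contain non-finite values")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    sbin = _bin_equal_width(scores, bins)
    vals = _voxel_matrix(np.asarray(batch, dtype=np.float64), mask)
    mi = _mi_values(vals, sbin, bins)
    out = np.zeros(mask.shape)
    out[mask] = mi
    return out


def permutation_pvalues(
    batch: np.ndarray,
    scores: np.ndarray,
    mask: np.ndarray,
    bins: int = 8,
    n_perm: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p-map for voxel-wise MI (scores permuted across subjects).

    Returns ``(mi_map, p_map, z_map)``.  P-values use the add-one rank
    formula ``(1 + #{perm >= obs}) / (1 + n_perm)`` so they lie in (0, 1].
    ``z_map`` standardizes the observed MI against the permutation-null
    moments, ``z = (MI - mean_null) / sd_null``; unlike the rank p-values
    (floored at ``1/(n_perm+1)``) it is not resolution-limited, so it is the
    statistic handed to the random-field correction.
    """
    scores = np.asarray(scores, dtype=np.float64)
    sbin = _bin_equal_width(scores, bins)
    vals = _voxel_matrix(np.asarray(batch, dtype=np.float64), mask)
    obs = _mi_values(vals, sbin, bins)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs)
    null_sum = np.zeros_like(obs)
    null_sq = np.zeros_like(obs)
    for _ in range(n_perm):
        perm = rng.permutation(len(scores))
        null = _mi_values(vals, sbin[perm], bins)
        exceed += null >= obs
        null_sum += null
        null_sq += null**2
    p = (1.0 + exceed) / (1.0 + n_perm)
    null_mean = null_sum / n_perm
    null_sd = np.sqrt(np.maximum(null_sq / n_perm - null_mean**2, 0.0))
    z = np.where(null_sd > 0, (obs - null_mean) / np.maximum(null_sd, 1e-12), 0.0)
    mi_map = np.zeros(mask.shape)
    mi_map[mask] = obs
    p_map = np.ones(mask.shape)
    p_map[mask] = p
    z_map = np.zeros(mask.shape)
    z_map[mask] = z
    return mi_map, p_map, z_map


def mi_significance(
    p_map: np.ndarray,
    mask: np.ndarray,
    fwhm,
    alpha: float = 0.05,
    z_map: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """GRF-corrected significance mask from the permutation stage.

    When ``z_map`` (permutation-null standardized MI) is given it is
    thresholded directly; otherwise p-values are converted to z-equivalents
    (z = Phi^-1(1 - p)) — note rank p-values are floored at 1/(n_perm+1),
    which caps that conversion.  Returns the binarized map used by
    Dice/Jaccard and the corrected z threshold.
    """
    if z_map is None:
        z_map = stats.norm.isf(np.clip(p_map, 1e-300, 1.0))
    return grf_correct(z_map, mask, fwhm, alpha=alpha)


@dataclass(frozen=True)
class MapSimilarity:
    dice: float
    jaccard: float
    ssim: float
    js: float


def dice_jaccard(x_mask: np.ndarray, y_mask: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x_mask, dtype=bool)
    y = np.asarray(y_mask, dtype=bool)
    nx, ny = int(x.sum()), int(y.sum())
    if nx == 0 and ny == 0:
        warnings.warn("both masks empty: Dice and Jaccard set to 0", stacklevel=2)
        return 0.0, 0.0
    inter = int((x & y).sum())
    union = int((x | y).sum())
    return 2.0 * inter / (nx + ny), inter / union


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    return np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)


def global_ssim(x: np.ndarray, y: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Global SSIM over in-mask voxels of min-max normalized maps (L = 1)."""
    if mask is not None:
        x, y = x[mask], y[mask]
    x = _minmax(np.asarray(x, dtype=np.float64).ravel())
    y = _minmax(np.asarray(y, dtype=np.float64).ravel())
    c1, c2 = 0.01**2, 0.03**2
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cxy = ((x - mx) * (y - my)).mean()
    return float(
        (2 * mx * my + c1) * (2 * cxy + c2) / ((mx**2 + my**2 + c1) * (vx + vy + c2))
    )


def js_divergence(x: np.ndarray, y: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Jensen-Shannon divergence (base 2, in [0, 1]) of sum-normalized maps."""
    if mask is not None:
        x, y = x[mask], y[mask]
    p = np.asarray(x, dtype=np.float64).ravel()
    q = np.asarray(y, dtype=np.float64).ravel()
    if p.min() < 0 or q.min() < 0:
        raise ValueError("JS divergence needs nonnegative maps")
    if p.sum() == 0 or q.sum() == 0:
        raise ValueError("cannot normalize an all-zero map")
    p, q = p / p.sum(), q / q.sum()
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_pm = np.where(p > 0, p * np.log2(p / m), 0.0).sum()
        kl_qm = np.where(q > 0, q * np.log2(q / m), 0.0).sum()
    return float(0.5 * kl_pm + 0.5 * kl_qm)


def map_similarity(
    map_x: np.ndarray,
    map_y: np.ndarray,
    mask_x: np.ndarray,
    mask_y: np.ndarray,
    analysis_mask: np.ndarray | None = None,
) -> MapSimilarity:
    """All four similarity metrics between two maps.

    Dice/Jaccard compare the binarized (significance) masks; SSIM and JS
    compare the continuous maps over the analysis mask.
    """
    d, j = dice_jaccard(mask_x, mask_y)
    return MapSimilarity(
        dice=d,
        jaccard=j,
        ssim=global_ssim(map_x, map_y, analysis_mask),
        js=js_divergence(map_x, map_y, analysis_mask),
    )


def pairwise_scale_similarity(
    maps: dict[str, np.ndarray],
    masks: dict[str, np.ndarray],
    analysis_mask: np.ndarray | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Symmetric scale-by-scale similarity matrices plus off-diagonal summary.

    Diagonals are the self-similarity values (1 for Dice/Jaccard/SSIM, 0 for
    JS); the summary reports mean and SD over off-diagonal pairs per metric.
    """
    names = list(maps)
    mats = {m: pd.DataFrame(np.eye(len(names)), index=names, columns=names) for m in ("dice", "jaccard", "ssim")}
    mats["js"] = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    vals: dict[str, list[float]] = {m: [] for m in mats}
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            sim = map_similarity(maps[a], maps[b], masks[a], masks[b], analysis_mask)
            for metric in mats:
                v = getattr(sim, metric)
                mats[metric].loc[a, b] = mats[metric].loc[b, a] = v
                vals[metric].append(v)
    summary = pd.DataFrame(
        {
            "metric": list(mats),
            "mean": [float(np.mean(vals[m])) if vals[m] else np.nan for m in mats],
            "sd": [float(np.std(vals[m])) if vals[m] else np.nan for m in mats],
        }
    )
    return mats, summary
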