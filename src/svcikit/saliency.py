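"""Guided-backpropagation saliency with group-level random-field inference.

Per subject, the gradient of the SVCI logit with respect to the input volume
is computed with double gating at every rectifier: relevance is propagated
only where the forward pre-activation was positive *and* the incoming
relevance is positive, so only positively contributing structure survives.
Channel gradients are summed into one voxel map and min-max normalized to
[0, 1] within the analysis mask.

Population-consistent salient regions are found by a voxel-wise one-sample
t-test across individual maps, converted to z scores and thresholded with a
Gaussian-random-field (GRF) family-wise correction based on the expected
Euler characteristic of a smooth 3D field.  Surviving voxels are projected
onto the white-matter atlas and ranked by normalized contribution weight.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import nn
from .densenet import DenseNet3D
from .io import region_project

__all__ = [
    "guided_backprop",
    "group_ttest",
    "estimate_fwhm",
    "grf_threshold",
    "grf_correct",
    "salient_regions",
]


def guided_backprop(
    model: DenseNet3D,
    batch: np.ndarray,
    target_class: int = 1,
    mask: np.ndarray | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Per-subject guided-backprop saliency maps for a channels-first batch.

    Returns an ``(N, X, Y, Z)`` array: the per-voxel sum over input channels
    of the absolute double-gated gradient of the ``target_class`` logit (SVCI
    by default), optionally min-max normalized to [0, 1] within ``mask``.
    Channels are aggregated by summed magnitude because channels whose
    pathological direction differs (anisotropy falls while diffusivity rises)
    carry input-layer gradients of opposite sign that would cancel under a
    signed sum.  Deterministic: the model runs in evaluation mode.
    """
    if not any(isinstance(m, nn.ReLU) for m in model.modules()):
        raise ValueError("guided backprop requires a model with rectified units")
    n = batch.shape[0]
    maps = np.empty((n,) + batch.shape[2:], dtype=np.float32)
    nn.set_guided(model, True)
    try:
        for i in range(n):
            logits = model.forward(batch[i : i + 1], train=False)
            seed = np.zeros_like(logits)
            seed[0, target_class] = 1.0
            gin = model.backward(seed)  # (1, C, X, Y, Z)
            maps[i] = np.abs(gin[0]).sum(axis=0)
    finally:
        nn.set_guided(model, False)
        for p in model.parameters():
            p.zero_grad()
    if normalize:
        for i in range(n):
            maps[i] = _minmax(maps[i], mask)
    return maps


def _minmax(vol: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    sel = mask if mask is not None else np.ones(vol.shape, dtype=bool)
    lo, hi = vol[sel].min(), vol[sel].max()
    if hi == lo:
        out = np.zeros_like(vol)
    else:
        out = (vol - lo) / (hi - lo)
    if mask is not None:
        out = np.where(mask, out, 0.0)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def group_ttest(maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-wise one-sample t statistics (against 0) across subject maps.

    Returns ``(t_map, valid)`` where ``valid`` flags voxels with nonzero
    variance; degenerate (zero-variance) voxels get ``t = 0`` and
    ``valid = False`` so they are excluded from inference.
    """
    maps = np.asarray(maps, dtype=np.float64)
    n = maps.shape[0]
    if n < 3:
        raise ValueError("need at least 3 maps for a group t-test")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    valid = sd > 0
    t = np.zeros_like(mean)
    np.divide(mean, sd / np.sqrt(n), out=t, where=valid)
    return t, valid


def estimate_fwhm(maps: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-axis smoothness (FWHM, voxels) of residual maps.

    Uses the derivative-variance relation for a smooth Gaussian field: after
    standardizing each residual map to unit variance within the mask, the
    variance of its spatial first differences along axis ``a`` estimates
    ``lambda_a``, and ``FWHM_a = sqrt(4 ln 2 / lambda_a)``.
    """
    maps = np.asarray(maps, dtype=np.float64)
    fwhm = np.empty(3)
    stand = []
    for m in maps:
        sd = m[mask].std()
        if sd == 0:
            continue
        stand.append((m - m[mask].mean()) / sd)
    if not stand:
        raise ValueError("all maps are constant inside the mask")
    for axis in range(3):
        num, den = 0.0, 0
        inner = np.logical_and(
            mask, np.roll(mask, -1, axis=axis)
        )  # both ends of each difference inside the mask
        inner = inner.take(range(mask.shape[axis] - 1), axis=axis)
        for u in stand:
            d = np.diff(u, axis=axis)[inner]
            num += float((d**2).sum())
            den += d.size
        lam = num / max(den, 1)
        fwhm[axis] = np.sqrt(4.0 * np.log(2.0) / lam) if lam > 0 else np.inf
    return fwhm


def _ec_density(z, d: int):
    """Expected Euler-characteristic density of a unit Gaussian field."""
    f = np.sqrt(4.0 * np.log(2.0))
    e = np.exp(-(z**2) / 2.0)
    if d == 0:
        return stats.norm.sf(z)
    if d == 1:
        return f / (2.0 * np.pi) * e
    if d == 2:
        return f**2 / (2.0 * np.pi) ** 1.5 * z * e
    if d == 3:
        return f**3 / (2.0 * np.pi) ** 2 * (z**2 - 1.0) * e
    raise ValueError(d)


def _resel_counts(mask: np.ndarray, fwhm: np.ndarray) -> np.ndarray:
    """Resel counts R_0..R_3, treating the mask as a box with matched volume.

    Side lengths come from the mask bounding box rescaled so the box volume
    equals the mask volume, then divided by the per-axis FWHM.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm, dtype=float), (3,))
    if not np.all(np.isfinite(fwhm)) or np.any(fwhm <= 0):
        raise ValueError(f"non-finite or non-positive smoothness: {fwhm}")
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise ValueError("empty mask")
    extent = idx.max(axis=0) - idx.min(axis=0) + 1.0
    vol = float(mask.sum())
    scale = (vol / extent.prod()) ** (1.0 / 3.0)
    sides = extent * scale / fwhm
    a, b, c = sides
    return np.array([1.0, a + b + c, a * b + a * c + b * c, a * b * c])


def grf_threshold(mask: np.ndarray, fwhm, alpha: float = 0.05) -> float:
    """One-sided z threshold controlling family-wise error via expected EC."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    resels = _resel_counts(mask, fwhm)
    # E[EC](z) is only monotone for z beyond ~sqrt(3) (the 3D density changes
    # sign at z=1); search a dense grid from the uncorrected threshold up and
    # take the first z whose expected EC drops to alpha
    z0 = float(stats.norm.isf(alpha))
    grid = np.linspace(z0, 12.0, 8192)
    ec = sum(resels[d] * _ec_density(grid, d) for d in range(4))
    below = np.nonzero(ec <= alpha)[0]
    if below.size == 0:
        return float(grid[-1])
    return float(grid[below[0]])


def grf_correct(
    stat_map: np.ndarray,
    mask: np.ndarray,
    fwhm,
    alpha: float = 0.05,
    df: int | None = None,
) -> tuple[np.ndarray, float]:
    """GRF-corrected significance mask for a t or z map.

    If ``df`` is given the map is treated as t-distributed and converted to z
    by matching tail probabilities; otherwise it is used as z directly.
    Returns ``(binary mask of surviving voxels, corrected z threshold)``.
    """
    z_map = np.asarray(stat_map, dtype=np.float64)
    if df is not None:
        with np.errstate(over="ignore"):
            z_map = stats.norm.isf(np.clip(stats.t.sf(z_map, df), 1e-300, 1.0))
    z_thr = grf_threshold(mask, fwhm, alpha)
    return (z_map >= z_thr) & mask, z_thr


def salient_regions(
    saliency_map: np.ndarray,
    significance_mask: np.ndarray,
    atlas: np.ndarray,
) -> pd.DataFrame:
    """Atlas regions containing surviving voxels, ranked by contribution weight.

    Weight is the region's share of total |saliency| over significant voxels;
    regions without surviving voxels are omitted, output sorted by descending
    weight.
    """
    if not significance_mask.any():
        warnings.warn("empty significance mask: no salient regions", stacklevel=2)
        return pd.DataFrame(
            columns=["region", "n_voxels", "sum", "mean", "weight"]
        )
    table = region_project(np.abs(saliency_map), atlas, significance_mask)
    table = table[table["n_voxels"] > 0]
    return table.sort_values("weight", ascending=False, ignore_index=True)
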