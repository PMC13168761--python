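"""SSIM-based multidomain cognitive risk stratification.

Each patient's guided-backprop saliency map is compared (global SSIM) with
each cognitive scale's MI map; higher SSIM means the model's decision for
that patient leans on white matter whose damage is most informative about
that cognitive domain — i.e. higher domain-specific risk.  Per scale, the
SSIM scores are clustered with 1-D K-means (K chosen by the elbow method,
clusters relabeled low/moderate/high by ascending mean) and cluster
differences are tested with Kruskal-Wallis followed by Dunn's pairwise test
with Bonferroni correction.

Caveat (documented, reproduced as published): testing SSIM differences
between clusters that were themselves derived from SSIM is circular, so the
tests are pipeline contracts rather than valid inference.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .mi import global_ssim, permutation_pvalues, mi_significance

__all__ = [
    "subject_scale_ssim",
    "elbow_k",
    "kmeans_stratify",
    "cluster_tests",
    "sensitivity_analysis",
]

RISK_LABELS_3 = ("low", "moderate", "high")


def subject_scale_ssim(
    saliency_maps: np.ndarray,
    mi_maps: dict[str, np.ndarray],
    mask: np.ndarray,
    smooth_sigma: float = 0.8,
) -> pd.DataFrame:
    """Subjects x scales matrix of global SSIM values.

    Both map families are lightly Gaussian-smoothed (``smooth_sigma`` voxels,
    0 disables) before comparison: guided-backprop maps carry high-frequency
    gating noise that is irrelevant to the regional alignment SSIM is meant
    to capture.  ``global_ssim`` min-max renormalizes internally.
    """
    for name, m in mi_maps.items():
        if m.shape != mask.shape or saliency_maps.shape[1:] != mask.shape:
            raise ValueError(f"grid mismatch for scale {name}")
    smoothed = [_smooth(s, smooth_sigma) for s in saliency_maps]
    out = {
        name: [global_ssim(s, _smooth(m, smooth_sigma), mask) for s in smoothed]
        for name, m in mi_maps.items()
    }
    return pd.DataFrame(out)


def _smooth(vol: np.ndarray, sigma: float) -> np.ndarray:
    from scipy import ndimage

    return vol if sigma <= 0 else ndimage.gaussian_filter(vol, sigma)


def _wcss(values: np.ndarray, k: int, seed: int = 0) -> float:
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(values.reshape(-1, 1))
    return float(km.inertia_)


def elbow_k(values: np.ndarray, k_max: int = 6, seed: int = 0) -> int:
    """Elbow choice of K: largest curvature of the within-cluster sum of
    squares over K = 1..k_max, ties toward smaller K.

    Curvature is taken on log WCSS so it is scale-invariant: the elbow is
    where the *relative* improvement collapses, which for well-separated
    clumps is exactly the true cluster count.
    """
    values = np.asarray(values, dtype=float).ravel()
    if len(np.unique(values)) < k_max + 1:
        raise ValueError(f"need more than {k_max} distinct values")
    wcss = np.array([_wcss(values, k, seed) for k in range(1, k_max + 1)])
    logw = np.log(np.maximum(wcss, 1e-12 * max(wcss[0], 1.0)))
    curv = [logw[k - 2] - 2 * logw[k - 1] + logw[k] for k in range(2, k_max)]
    return int(np.argmax(curv) + 2)


def kmeans_stratify(
    values: np.ndarray, k: int, seed: int = 0, n_init: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """1-D K-means with k-means++ restarts; clusters ordered by ascending mean.

    Returns ``(labels, ordered_means)`` where labels are 'low'/'moderate'/
    'high' for K = 3 and 'level_1..K' otherwise.  Ties on cluster mean are
    broken by descending cluster size.
    """
    values = np.asarray(values, dtype=float).ravel()
    if k < 2:
        raise ValueError("K must be >= 2")
    if len(np.unique(values)) < k:
        raise ValueError("K exceeds the number of distinct values")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(
        values.reshape(-1, 1)
    )
    raw = km.labels_
    means = np.array([values[raw == c].mean() for c in range(k)])
    sizes = np.array([(raw == c).sum() for c in range(k)])
    order = np.lexsort((-sizes, means))
    names = RISK_LABELS_3 if k == 3 else tuple(f"level_{i + 1}" for i in range(k))
    remap = {int(c): names[rank] for rank, c in enumerate(order)}
    labels = np.array([remap[int(c)] for c in raw])
    return labels, means[order]


def _dunn_pairwise(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's rank-based pairwise z tests with tie correction."""
    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    names = sorted(set(groups.tolist()))
    mean_ranks = {g: ranks[groups == g].mean() for g in names}
    sizes = {g: int((groups == g).sum()) for g in names}
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in combinations(names, 2):
        se = np.sqrt(
            (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "z": float(z),
                "p_raw": float(p),
                "p_bonferroni": float(min(1.0, p * n_pairs)),
            }
        )
    return pd.DataFrame(rows)


def cluster_tests(values: np.ndarray, labels: np.ndarray) -> dict:
    """Kruskal-Wallis across clusters plus Dunn/Bonferroni pairwise table."""
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in sorted(set(labels.tolist()))]
    if len(groups) < 2 or min(len(g) for g in groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    h, p = stats.kruskal(*groups)
    return {
        "kruskal_h": float(h),
        "kruskal_p": float(p),
        "dunn": _dunn_pairwise(values, labels),
    }


def sensitivity_analysis(
    batch: np.ndarray,
    scores: pd.DataFrame,
    saliency_maps: np.ndarray,
    mask: np.ndarray,
    fwhm,
    fraction: float = 0.8,
    seed: int = 0,
    bins: int = 8,
    n_perm: int = 100,
    k: int = 3,
    alpha: float = 0.05,
    smooth_sigma: float = 0.8,
) -> pd.DataFrame:
    """Stability of SSIM clustering when MI maps come from a subject subsample.

    Rebuilds each scale's MI map from a random ``fraction`` of subjects,
    recomputes every subject's SSIM against the subsample map, reclusters,
    and reports per scale: cluster-wise mean SSIM (full and subsample), the
    fraction of subjects changing cluster, and the Spearman correlation
    between full-sample and subsample SSIM vectors.
    """
    n = batch.shape[0]
    n_sub = int(round(fraction * n))
    if n_sub < 10:
        raise ValueError("subsample must keep at least 10 subjects")
    rng = np.random.default_rng(seed)
    subset = (
        np.arange(n) if n_sub == n else np.sort(rng.choice(n, n_sub, replace=False))
    )
    rows = []
    for scale in scores.columns:
        full_mi, _, _ = permutation_pvalues(
            batch, scores[scale].to_numpy(), mask, bins=bins, n_perm=n_perm, seed=seed
        )
        sub_mi, _, _ = permutation_pvalues(
            batch[subset],
            scores[scale].to_numpy()[subset],
            mask,
            bins=bins,
            n_perm=n_perm,
            seed=seed,
        )
        sm_sal = [_smooth(s, smooth_sigma) for s in saliency_maps]
        sm_full = _smooth(full_mi, smooth_sigma)
        sm_sub = _smooth(sub_mi, smooth_sigma)
        ssim_full = np.array([global_ssim(s, sm_full, mask) for s in sm_sal])
        ssim_sub = np.array([global_ssim(s, sm_sub, mask) for s in sm_sal])
        lab_full, _ = kmeans_stratify(ssim_full, k, seed=seed)
        lab_sub, _ = kmeans_stratify(ssim_sub, k, seed=seed)
        if np.array_equal(ssim_full, ssim_sub):
            rho = 1.0
        else:
            rho = float(stats.spearmanr(ssim_full, ssim_sub).statistic)
        row = {
            "scale": scale,
            "change_rate": float(np.mean(lab_full != lab_sub)),
            "spearman_r": rho,
        }
        for lab in sorted(set(lab_full.tolist())):
            row[f"mean_ssim_full_{lab}"] = float(ssim_full[lab_full == lab].mean())
        for lab in sorted(set(lab_sub.tolist())):
            row[f"mean_ssim_sub_{lab}"] = float(ssim_sub[lab_sub == lab].mean())
        rows.append(row)
    return pd.DataFrame(rows)
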