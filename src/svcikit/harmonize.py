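"""ComBat-style empirical-Bayes harmonization of site (scanner) effects.

Location/scale model with parametric priors: features are standardized
against a site-free linear model (intercept plus optional covariates), then
per-site location shifts (normal prior) and scale factors (inverse-gamma
prior) are shrunk toward their across-feature pooled estimates and removed.
Parameters are fitted on training data only and applied unchanged to
held-out data, so test subjects never influence the harmonization.

Features are a reduced representation (per-atlas-region channel means or
down-sampled voxels) rather than full-resolution voxel maps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CombatParams", "combat_fit", "combat_apply", "regional_features"]


@dataclass
class CombatParams:
    sites: list[str]
    alpha: np.ndarray            # feature grand means, shape (p,)
    beta: np.ndarray             # covariate coefficients, shape (q, p)
    var_pooled: np.ndarray       # pooled feature variance, shape (p,)
    gamma_star: np.ndarray       # EB site location effects, shape (s, p)
    delta_sq_star: np.ndarray    # EB site scale effects (>0), shape (s, p)
    kept: np.ndarray             # boolean mask of harmonized (non-constant) features

    def to_json(self) -> str:
        return json.dumps(
            {
                "sites": self.sites,
                "alpha": self.alpha.tolist(),
                "beta": self.beta.tolist(),
                "var_pooled": self.var_pooled.tolist(),
                "gamma_star": self.gamma_star.tolist(),
                "delta_sq_star": self.delta_sq_star.tolist(),
                "kept": self.kept.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CombatParams":
        d = json.loads(text)
        return cls(
            sites=d["sites"],
            alpha=np.array(d["alpha"]),
            beta=np.array(d["beta"]),
            var_pooled=np.array(d["var_pooled"]),
            gamma_star=np.array(d["gamma_star"]),
            delta_sq_star=np.array(d["delta_sq_star"]),
            kept=np.array(d["kept"], dtype=bool),
        )


def _site_design(site_labels, sites) -> np.ndarray:
    d = np.zeros((len(site_labels), len(sites)))
    for j, s in enumerate(sites):
        d[np.asarray(site_labels) == s, j] = 1.0
    return d


def combat_fit(
    features: np.ndarray,
    site_labels,
    covariates: np.ndarray | None = None,
    eb_iters: int = 100,
    tol: float = 1e-6,
) -> CombatParams:
    """Fit location/scale site-effect parameters with empirical-Bayes shrinkage."""
    y = np.asarray(features, dtype=float)
    if y.ndim != 2:
        raise ValueError("features must be a subjects x features matrix")
    n, p = y.shape
    site_labels = np.asarray(site_labels)
    sites = sorted(set(site_labels.tolist()))
    if len(sites) < 2:
        raise ValueError("ComBat needs at least two sites")
    counts = {s: int((site_labels == s).sum()) for s in sites}
    if min(counts.values()) < 3:
        raise ValueError(f"each site needs >= 3 subjects, got {counts}")

    kept = y.std(axis=0) > 0
    if not kept.all():
        warnings.warn(
            f"dropping {int((~kept).sum())} constant feature(s) from harmonization",
            stacklevel=2,
        )
    yk = y[:, kept]

    d_site = _site_design(site_labels, sites)
    q = 0 if covariates is None else np.atleast_2d(np.asarray(covariates, float)).shape[1]
    cov = (
        np.empty((n, 0))
        if covariates is None
        else np.asarray(covariates, float).reshape(n, q)
    )
    design = np.hstack([d_site, cov])
    b_hat, *_ = np.linalg.lstsq(design, yk, rcond=None)
    frac = np.array([counts[s] / n for s in sites])
    alpha = frac @ b_hat[: len(sites)]                     # grand mean per feature
    beta = b_hat[len(sites):]
    resid = yk - design @ b_hat
    var_pooled = (resid**2).mean(axis=0)
    var_pooled = np.maximum(var_pooled, 1e-12)

    stand = (yk - alpha - cov @ beta) / np.sqrt(var_pooled)

    gamma_hat = np.stack([stand[site_labels == s].mean(axis=0) for s in sites])
    delta_sq_hat = np.stack(
        [stand[site_labels == s].var(axis=0, ddof=1) for s in sites]
    )
    delta_sq_hat = np.maximum(delta_sq_hat, 1e-12)

    # parametric EB priors: normal across features for location,
    # inverse-gamma (moment-matched) for scale
    gamma_bar = gamma_hat.mean(axis=1)
    tau_sq = gamma_hat.var(axis=1, ddof=1)
    m = delta_sq_hat.mean(axis=1)
    v = delta_sq_hat.var(axis=1, ddof=1)
    v = np.maximum(v, 1e-12)
    a_prior = (2 * v + m**2) / v
    b_prior = (m * v + m**3) / v

    gamma_star = gamma_hat.copy()
    delta_sq_star = delta_sq_hat.copy()
    for i, s in enumerate(sites):
        ns = counts[s]
        z = stand[site_labels == s]
        g, dsq = gamma_hat[i].copy(), delta_sq_hat[i].copy()
        for _ in range(eb_iters):
            g_new = (ns * tau_sq[i] * gamma_hat[i] + dsq * gamma_bar[i]) / (
                ns * tau_sq[i] + dsq
            )
            ss = ((z - g_new) ** 2).sum(axis=0)
            dsq_new = (b_prior[i] + 0.5 * ss) / (ns / 2.0 + a_prior[i] - 1.0)
            change = max(
                np.abs(g_new - g).max(initial=0.0),
                np.abs(dsq_new - dsq).max(initial=0.0),
            )
            g, dsq = g_new, dsq_new
            if change < tol:
                break
        gamma_star[i] = g
        delta_sq_star[i] = np.maximum(dsq, 1e-12)

    return CombatParams(
        sites=sites,
        alpha=alpha,
        beta=beta,
        var_pooled=var_pooled,
        gamma_star=gamma_star,
        delta_sq_star=delta_sq_star,
        kept=kept,
    )


def combat_apply(
    features: np.ndarray,
    site_labels,
    params: CombatParams,
    covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Remove fitted site effects from (possibly held-out) data."""
    y = np.asarray(features, dtype=float)
    n = y.shape[0]
    site_labels = np.asarray(site_labels)
    unseen = set(site_labels.tolist()) - set(params.sites)
    if unseen:
        raise ValueError(f"no fitted parameters for site(s) {sorted(unseen)}")
    q = params.beta.shape[0]
    cov = np.empty((n, 0)) if q == 0 else np.asarray(covariates, float).reshape(n, q)
    out = y.copy()
    yk = y[:, params.kept]
    stand = (yk - params.alpha - cov @ params.beta) / np.sqrt(params.var_pooled)
    adj = np.empty_like(stand)
    for i, s in enumerate(params.sites):
        sel = site_labels == s
        if not sel.any():
            continue
        adj[sel] = (stand[sel] - params.gamma_star[i]) / np.sqrt(
            params.delta_sq_star[i]
        )
    out[:, params.kept] = adj * np.sqrt(params.var_pooled) + params.alpha + cov @ params.beta
    return out


def regional_features(
    batch: np.ndarray, atlas: np.ndarray
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Per-atlas-region channel means: ``(N, C, X, Y, Z)`` -> ``(N, C*R)``.

    Returns the feature matrix and the (channel, region) pair for each column.
    """
    labels = np.unique(atlas)
    labels = labels[labels > 0]
    n, c = batch.shape[:2]
    feats = np.empty((n, c * len(labels)))
    names = []
    for j, lab in enumerate(labels):
        sel = atlas == lab
        for ch in range(c):
            feats[:, ch * len(labels) + j] = batch[:, ch][:, sel].mean(axis=1)
    for ch in range(c):
        names.extend((ch, int(lab)) for lab in labels)
    return feats, names
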