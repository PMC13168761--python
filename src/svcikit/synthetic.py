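"""Two-site, two-group synthetic DTI cohorts with planted lesion patterns.

The generator emulates the structure of a two-center vascular-cognitive-
impairment study: SVCI and SIVD groups scanned at an internal and an external
site, with four diffusion scalar channels (FA, MD, AD, RD) on a common grid,
a white-matter parcellation, and six neuropsychological scores driven by
regional lesion severity.

Baseline volumes are smoothed Gaussian noise fields offset to channel-typical
positive levels (smoothness is what downstream Gaussian-random-field
inference assumes).  Each SVCI subject draws a nonnegative, right-skewed
per-region lesion severity (Gamma, shape 2), which lowers FA and raises
diffusivities inside the lesion regions; SIVD subjects have severity
identically zero.  The external site applies an additive offset and a
multiplicative scale to every volume, the harmonization module's target.
Scores follow each scale's clinical sign convention: higher MMSE/MoCA/Recall
is better, longer TMT-A/TMT-B completion times are worse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import CHANNELS, SCALE_SIGNS, SCALES, ScalarVolumeSet, save_volume, write_cohort

__all__ = [
    "ScoreModel",
    "SyntheticConfig",
    "SubjectRecord",
    "default_score_models",
    "generate_atlas",
    "generate_cohort",
    "export_cohort",
]

#: Channel-typical baseline levels (FA dimensionless; diffusivities in
#: 10^-3 mm^2/s) and the direction/relative size of the planted lesion effect:
#: FA falls while MD/AD/RD rise in damaged white matter, radial diffusivity
#: more than axial.
BASELINES = {"FA": 0.45, "MD": 0.80, "AD": 1.20, "RD": 0.60}
EFFECT_PATTERN = {"FA": -1.0, "MD": +1.0, "AD": +0.5, "RD": +0.75}


@dataclass(frozen=True)
class ScoreModel:
    """Linear lesion-to-score model for one neuropsychological scale.

    ``score = intercept - sign * sum(weights * severity) + noise``, clamped to
    ``clamp``.  With positive weights, +1-signed scales (MMSE, MoCA, Recalls)
    decrease as lesions worsen while -1-signed timed tests (TMT-A/B) increase.
    """

    intercept: float
    weights: tuple[float, ...]
    noise_sd: float
    sign: int
    clamp: tuple[float, float]


def default_score_models(lesion_regions: tuple[int, ...]) -> dict[str, ScoreModel]:
    """Per-scale weight patterns over the lesion regions.

    Each scale concentrates its weight on a different lesion region (cycling
    when there are fewer regions than scales) so that the six MI maps have
    distinct spatial supports, mirroring domain-specific structural
    correlates.  Intercepts and ranges are typical clinical values.
    """
    n = len(lesion_regions)
    base = {
        "MMSE": (29.0, 2.0, 1.0, (0.0, 30.0)),
        "MoCA": (27.0, 3.0, 1.5, (0.0, 30.0)),
        "Immediate Recall": (30.0, 5.0, 3.0, (0.0, 44.0)),
        "Delayed Recall": (12.0, 3.0, 1.5, (0.0, 15.0)),
        "TMT-A": (45.0, 25.0, 10.0, (20.0, 300.0)),
        "TMT-B": (80.0, 50.0, 20.0, (30.0, 400.0)),
    }
    models = {}
    for s, scale in enumerate(SCALES):
        intercept, magnitude, noise_sd, clamp = base[scale]
        w = np.full(n, 0.25)
        w[s % n] = 1.0
        w = w / w.sum() * magnitude
        models[scale] = ScoreModel(
            intercept=intercept,
            weights=tuple(float(v) for v in w),
            noise_sd=noise_sd,
            sign=SCALE_SIGNS[scale],
            clamp=clamp,
        )
    return models


@dataclass(frozen=True)
class SyntheticConfig:
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    n_per_cell: int = 30
    n_regions: int = 11
    lesion_regions: tuple[int, ...] = (1, 2, 3)
    effect_size: dict = field(default_factory=lambda: dict(EFFECT_PATTERN))
    site_shift: dict = field(
        default_factory=lambda: {"internal": (0.0, 1.0), "external": (0.2, 1.1)}
    )
    #: amplitude of the external site's smooth multiplicative bias field
    #: (scanner-like spatially varying gain); unlike the global affine shift,
    #: it survives per-sample z-normalization and is what makes the domain
    #: shift visible to the classifier
    site_bias_amp: float = 0.25
    noise_sd: float = 0.10
    smoothing_fwhm: float = 3.0
    severity_scale: float = 0.5
    severity_tiers: tuple[float, ...] | None = None
    tier_mode: str = "extent"  # "extent": tiers lesion progressively more
    # regions at fixed amplitude (lesion burden spreads with severity);
    # "amplitude": tiers scale per-region severity uniformly
    tier_jitter: float = 0.10
    score_models: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        if not self.lesion_regions:
            raise ValueError("lesion_regions must be non-empty")
        if max(self.lesion_regions) > self.n_regions:
            raise ValueError("lesion_regions must exist in the atlas")
        if self.effect_size.get("FA", 0.0) > 0:
            raise ValueError("FA effect must be <= 0 (anisotropy falls with damage)")
        if self.effect_size.get("MD", 0.0) < 0:
            raise ValueError("MD effect must be >= 0 (diffusivity rises with damage)")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    site: str
    severity: dict[int, float]
    volumes: ScalarVolumeSet
    scores: dict[str, float]
    tier: int | None = None  # planted severity tier index, if tiers were used


def generate_atlas(
    grid_shape: tuple[int, int, int], n_regions: int, seed: int = 0
) -> np.ndarray:
    """Partition a central ellipsoidal white-matter mask into contiguous parcels.

    Parcels are nearest-seed (Voronoi) cells of randomly placed seed voxels;
    because the mask is convex each cell is spatially contiguous.  Label 0 is
    background, labels ``1..n_regions`` partition the mask.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    shape = tuple(int(s) for s in grid_shape)
    grids = np.indices(shape).astype(float)
    center = (np.array(shape) - 1) / 2.0
    semi = np.maximum(np.array(shape) * 0.38, 1.0)
    d2 = sum(((grids[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    mask = d2 <= 1.0
    n_mask = int(mask.sum())
    if n_mask < 4 * n_regions:
        raise ValueError(
            f"grid {shape} too small to host {n_regions} parcels "
            f"({n_mask} mask voxels)"
        )
    rng = np.random.default_rng(seed)
    coords = np.argwhere(mask)
    seeds = coords[rng.choice(n_mask, size=n_regions, replace=False)]
    dists = np.linalg.norm(coords[:, None, :] - seeds[None, :, :], axis=2)
    labels = dists.argmin(axis=1) + 1
    atlas = np.zeros(shape, dtype=np.int16)
    atlas[tuple(coords.T)] = labels
    return atlas


def _smooth_field(rng: np.random.Generator, shape, fwhm: float) -> np.ndarray:
    """Unit-variance smoothed Gaussian noise field."""
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    return (f - f.mean()) / f.std()


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[SubjectRecord], np.ndarray]:
    """Generate ``2 groups x 2 sites x n_per_cell`` subjects plus the atlas.

    Identical seeds give bit-identical cohorts.  The planted effect shifts
    in-lesion voxel means by ``effect_size[channel] * noise_sd * severity``,
    i.e. the effect size is expressed in units of the (pre-smoothing) voxel
    noise standard deviation.
    """
    atlas = generate_atlas(config.grid_shape, config.n_regions, seed=config.seed)
    mask = atlas > 0
    region_masks = {r: atlas == r for r in config.lesion_regions}
    score_models = config.score_models or default_score_models(config.lesion_regions)
    rng = np.random.default_rng(config.seed)
    # one fixed smooth gain field per site (scanner signature), shared by all
    # subjects scanned there
    bias_rng = np.random.default_rng(config.seed + 1)
    bias_field = _smooth_field(
        bias_rng, config.grid_shape, 2.0 * config.smoothing_fwhm
    )
    site_gain = {
        "internal": np.ones(config.grid_shape),
        "external": 1.0 + config.site_bias_amp * bias_field,
    }
    records: list[SubjectRecord] = []
    counter = 0
    for group in ("SVCI", "SIVD"):
        for site in ("internal", "external"):
            for k in range(config.n_per_cell):
                counter += 1
                sid = f"sub-{counter:04d}"
                tier_idx: int | None = None
                if group == "SVCI":
                    if config.severity_tiers is not None:
                        tier_idx = k % len(config.severity_tiers)
                        # discrete severity tiers (round-robin) with small
                        # multiplicative jitter: planted ground truth for
                        # risk stratification
                        tier = config.severity_tiers[tier_idx]
                        jit = lambda v: float(
                            max(0.0, v * (1.0 + config.tier_jitter * rng.standard_normal()))
                        )
                        if config.tier_mode == "extent":
                            # lesion burden spreads over more regions as the
                            # tier rises; amplitude fixed by the tier value
                            n_hit = int(
                                np.ceil(
                                    (tier_idx + 1)
                                    * len(config.lesion_regions)
                                    / len(config.severity_tiers)
                                )
                            )
                            severity = {
                                r: jit(tier) if i < n_hit else 0.0
                                for i, r in enumerate(config.lesion_regions)
                            }
                        elif config.tier_mode == "amplitude":
                            severity = {r: jit(tier) for r in config.lesion_regions}
                        else:
                            raise ValueError(
                                f"unknown tier_mode {config.tier_mode!r}"
                            )
                    else:
                        severity = {
                            r: float(rng.gamma(2.0, config.severity_scale))
                            for r in config.lesion_regions
                        }
                else:
                    severity = {r: 0.0 for r in config.lesion_regions}
                # focal lesion texture: one subject-specific blob field
                # modulates the planted shift so lesions are patchy (like
                # white-matter hyperintensities), mean shift preserved
                blob = np.maximum(
                    _smooth_field(rng, config.grid_shape, config.smoothing_fwhm), 0.0
                )
                channels = {}
                for ch in CHANNELS:
                    vol = BASELINES[ch] + config.noise_sd * _smooth_field(
                        rng, config.grid_shape, config.smoothing_fwhm
                    )
                    eff = config.effect_size.get(ch, 0.0)
                    if eff:
                        for r, sev in severity.items():
                            if sev == 0.0:
                                continue
                            sel = region_masks[r]
                            mod = blob[sel]
                            mod = mod / mod.mean() if mod.mean() > 0 else 1.0
                            vol[sel] += eff * config.noise_sd * sev * mod
                    offset, scale = config.site_shift[site]
                    channels[ch] = (
                        (vol * scale + offset) * site_gain[site]
                    ).astype(np.float32)
                sev_vec = np.array([severity[r] for r in config.lesion_regions])
                scores = {}
                for scale_name, sm in score_models.items():
                    if len(sm.weights) != len(config.lesion_regions):
                        raise ValueError(
                            f"score model for {scale_name} has "
                            f"{len(sm.weights)} weights for "
                            f"{len(config.lesion_regions)} lesion regions"
                        )
                    raw = (
                        sm.intercept
                        - sm.sign * float(np.dot(sm.weights, sev_vec))
                        + rng.normal(0.0, sm.noise_sd)
                    )
                    scores[scale_name] = float(np.clip(raw, *sm.clamp))
                records.append(
                    SubjectRecord(
                        subject_id=sid,
                        group=group,
                        site=site,
                        severity=severity,
                        volumes=ScalarVolumeSet(
                            channels=channels, mask=mask.copy()
                        ),
                        scores=scores,
                        tier=tier_idx,
                    )
                )
    return records, atlas


def cohort_table(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "site": rec.site,
            "split": "",
            "severity_total": float(sum(rec.severity.values())),
        }
        row.update(rec.scores)
        rows.append(row)
    return pd.DataFrame(rows)


def export_cohort(records: list[SubjectRecord], atlas: np.ndarray, outdir) -> Path:
    """Write per-subject per-channel NIfTI volumes, the atlas, and cohort.csv."""
    outdir = Path(outdir)
    (outdir / "volumes").mkdir(parents=True, exist_ok=True)
    for rec in records:
        for ch, vol in rec.volumes.channels.items():
            save_volume(
                outdir / "volumes" / f"{rec.subject_id}_{ch}.nii.gz",
                vol,
                rec.volumes.affine,
            )
    save_volume(outdir / "atlas.nii.gz", atlas.astype(np.float32))
    write_cohort(cohort_table(records), outdir / "cohort.csv")
    return outdir
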