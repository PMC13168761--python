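"""Volume and cohort-table I/O, channel stacking, normalization, atlas projection.

Conventions
-----------
* Channel order is canonical ``(FA, MD, AD, RD)``; any user-supplied subset is
  re-ordered into it, so ``(MD, FA)`` and ``(FA, MD)`` produce identical
  tensors.
* Voxel indices are 0-based; affines are carried through untouched and all
  computation happens in voxel space (spatial normalization to a common
  MNI-like grid is assumed done upstream).
* The default white-matter analysis mask is ``atlas > 0``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

CHANNELS = ("FA", "MD", "AD", "RD")

SCALES = (
    "MMSE",
    "MoCA",
    "Immediate Recall",
    "Delayed Recall",
    "TMT-A",
    "TMT-B",
)
#: +1 when higher scores mean better cognition, -1 for timed tests where
#: longer completion times mean worse executive function.
SCALE_SIGNS = {
    "MMSE": +1,
    "MoCA": +1,
    "Immediate Recall": +1,
    "Delayed Recall": +1,
    "TMT-A": -1,
    "TMT-B": -1,
}

__all__ = [
    "CHANNELS",
    "SCALES",
    "SCALE_SIGNS",
    "ScalarVolumeSet",
    "all_combinations",
    "canonicalize_combination",
    "stack_combination",
    "normalize_intensity",
    "region_project",
    "impute_means",
    "load_volume",
    "save_volume",
    "read_cohort",
    "write_cohort",
]


@dataclass
class ScalarVolumeSet:
    """Per-subject multi-channel 3D diffusion scalar maps on a shared grid."""

    channels: dict[str, np.ndarray]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self):
        shapes = {ch: v.shape for ch, v in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channels disagree on grid shape: {shapes}")
        for ch in self.channels:
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel {ch!r}; expected subset of {CHANNELS}")
        if self.mask is not None:
            for ch, v in self.channels.items():
                if self.mask.shape != v.shape:
                    raise ValueError("mask shape does not match channel grid")
                if not np.all(np.isfinite(v[self.mask])):
                    raise ValueError(f"non-finite values inside mask in channel {ch}")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape


def all_combinations() -> list[tuple[str, ...]]:
    """The 15 non-empty channel subsets, in canonical channel order."""
    out = []
    for r in range(1, len(CHANNELS) + 1):
        out.extend(itertools.combinations(CHANNELS, r))
    return out


def canonicalize_combination(combination) -> tuple[str, ...]:
    combo = tuple(combination)
    if not combo:
        raise ValueError("combination must be non-empty")
    if len(set(combo)) != len(combo):
        raise ValueError(f"duplicate channels in {combo}")
    for ch in combo:
        if ch not in CHANNELS:
            raise ValueError(f"unknown channel {ch!r}")
    return tuple(ch for ch in CHANNELS if ch in combo)


def stack_combination(
    volume_sets: list[ScalarVolumeSet], combination
) -> np.ndarray:
    """Stack subjects into a ``(N, C, X, Y, Z)`` batch for a channel subset."""
    combo = canonicalize_combination(combination)
    if not volume_sets:
        raise ValueError("no subjects given")
    shape = volume_sets[0].shape
    batch = np.empty((len(volume_sets), len(combo)) + shape, dtype=np.float32)
    for i, vs in enumerate(volume_sets):
        if vs.shape != shape:
            raise ValueError(f"subject {i} grid {vs.shape} != {shape}")
        for j, ch in enumerate(combo):
            if ch not in vs.channels:
                raise ValueError(f"subject {i} is missing channel {ch}")
            batch[i, j] = vs.channels[ch]
    return batch


def normalize_intensity(
    batch: np.ndarray,
    mask: np.ndarray | None = None,
    fit_scope: str = "per_sample",
    log: list | None = None,
) -> np.ndarray:
    """Z-score each sample-channel over in-mask voxels, independently per sample.

    Because statistics are computed per sample, normalizing the training and
    test sets in separate calls can never share state; ``log`` (if given)
    records each call for auditability.
    """
    if fit_scope != "per_sample":
        raise ValueError("only per_sample normalization is supported")
    batch = np.asarray(batch, dtype=np.float32)
    if mask is None:
        mask = np.ones(batch.shape[2:], dtype=bool)
    out = np.empty_like(batch)
    for i in range(batch.shape[0]):
        for c in range(batch.shape[1]):
            vals = batch[i, c][mask]
            sd = vals.std()
            if sd == 0:
                raise ValueError(
                    f"zero in-mask variance for sample {i}, channel {c}"
                )
            out[i, c] = (batch[i, c] - vals.mean()) / sd
    if log is not None:
        log.append({"n_samples": int(batch.shape[0]), "fit_scope": fit_scope})
    return out


def region_project(
    voxel_map: np.ndarray,
    atlas: np.ndarray,
    significance_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Summarize a voxel map over atlas regions restricted to significant voxels.

    Returns one row per region with the count of significant voxels, the sum
    and mean of map values over them, and the normalized contribution weight
    (region sum / total sum over all significant voxels).
    """
    if voxel_map.shape != atlas.shape:
        raise ValueError("map and atlas grids differ")
    if significance_mask is None:
        significance_mask = np.ones_like(atlas, dtype=bool)
    rows = []
    labels = np.unique(atlas)
    labels = labels[labels > 0]
    sel_all = significance_mask & (atlas > 0)
    total = float(np.abs(voxel_map[sel_all]).sum())
    if total == 0.0:
        warnings.warn("no significant voxels overlap the atlas", stacklevel=2)
    for lab in labels:
        sel = (atlas == lab) & significance_mask
        n = int(sel.sum())
        s = float(np.abs(voxel_map[sel]).sum()) if n else 0.0
        rows.append(
            {
                "region": int(lab),
                "n_voxels": n,
                "sum": s,
                "mean": s / n if n else 0.0,
                "weight": s / total if total > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def impute_means(table: pd.DataFrame) -> pd.DataFrame:
    """Fill missing numeric entries with the column mean of observed values."""
    out = table.copy()
    for col in out.columns:
        if not pd.api.types.is_numeric_dtype(out[col]):
            continue
        if out[col].isna().all():
            raise ValueError(f"column {col!r} has no observed values to average")
        out[col] = out[col].fillna(out[col].mean())
    return out


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float32), img.affine


def save_volume(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def read_cohort(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in cohort table")
    bad = set(df["group"].unique()) - {"SVCI", "SIVD"}
    if bad:
        raise ValueError(f"unknown group labels: {bad}")
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
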