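"""Shared fixtures.

The expensive end-to-end artifacts (synthetic cohort, trained classifier,
saliency and MI maps) are built once per session at desk scale and shared by
the tests that probe different facets of the same workflow.
"""

from __future__ import annotations

import numpy as np
import pytest

from svcikit import io as vio
from svcikit import saliency, synthetic
from svcikit.densenet import (
    DenseNetConfig,
    TrainConfig,
    build_model,
    predict_proba,
    split_and_cv,
    train,
)

DESK_NET = dict(init_filters=24, growth=12)
DESK_TRAIN = dict(epochs=20, lr=1e-3)


@pytest.fixture(scope="session")
def small_cohort():
    """Cheap 2-site cohort (no training involved)."""
    cfg = synthetic.SyntheticConfig(
        grid_shape=(16, 16, 16),
        n_per_cell=12,
        n_regions=8,
        lesion_regions=(1, 2, 3),
        seed=7,
    )
    records, atlas = synthetic.generate_cohort(cfg)
    return cfg, records, atlas


@pytest.fixture(scope="session")
def e2e():
    """Trained desk-scale classifier plus downstream artifacts.

    Cohort with planted 1-SD lesion effects and three severity tiers; the
    classifier is trained on the internal site's training split.
    """
    cfg = synthetic.SyntheticConfig(
        grid_shape=(16, 16, 16),
        n_per_cell=60,
        n_regions=8,
        lesion_regions=(1, 2, 3),
        severity_tiers=(2.0, 2.0, 2.0),
        tier_mode="extent",
        tier_jitter=0.05,
        seed=1,
    )
    records, atlas = synthetic.generate_cohort(cfg)
    mask = atlas > 0
    labels = np.array([1 if r.group == "SVCI" else 0 for r in records])
    site = np.array([r.site for r in records])
    internal = np.where(site == "internal")[0]
    batch = vio.stack_combination([r.volumes for r in records], ("FA", "MD"))
    x = vio.normalize_intensity(batch)
    split = split_and_cv(labels[internal], seed=0)
    tr = internal[split["train"]]
    te = internal[split["test"]]
    model = build_model(DenseNetConfig(in_channels=2, **DESK_NET), seed=0)
    train(model, x[tr], labels[tr], TrainConfig(seed=0, **DESK_TRAIN))
    svci_internal = internal[labels[internal] == 1]
    smaps = saliency.guided_backprop(model, x[svci_internal], mask=mask)
    table = synthetic.cohort_table(records)
    scores = table.loc[list(svci_internal), list(vio.SCALES)].reset_index(drop=True)
    return {
        "config": cfg,
        "records": records,
        "atlas": atlas,
        "mask": mask,
        "labels": labels,
        "site": site,
        "internal": internal,
        "external": np.where(site == "external")[0],
        "batch": batch,
        "x": x,
        "train_idx": tr,
        "test_idx": te,
        "model": model,
        "probs_test": predict_proba(model, x[te]),
        "saliency": smaps,
        "svci_internal": svci_internal,
        "scores": scores,
        "tiers": np.array([records[i].tier for i in svci_internal]),
        "table": table,
    }
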