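"""Domain-adversarial unsupervised domain adaptation (DANN) for the classifier.

A shared feature extractor ``F`` (the DenseNet trunk up to global pooling)
feeds two heads: the SVCI classifier ``C`` and a domain classifier ``D``
attached through a gradient reversal layer (GRL).  Training jointly minimizes
the source-domain classification loss and maximizes the domain classifier's
confusion: the GRL is the identity forward and multiplies the incoming
gradient by ``-lambda`` backward, pushing ``F`` toward site-invariant
features.

The adversarial weight follows the logistic schedule
``lambda(p) = 2 / (1 + exp(-5 p)) - 1`` with training progress
``p = (i + epoch * N_iter) / (N_epoch * N_iter)`` rising linearly from 0 to 1,
so adaptation is gentle early and strong late.  The total loss is
``L_cls_source + alpha * (L_dom_source + L_dom_target)`` with ``alpha = 0.1``.
Each iteration draws one source and one target mini-batch of identical size;
iterations per epoch are set by the smaller domain.  Target labels are never
read: the training routine does not accept them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .densenet import DenseNet3D

__all__ = [
    "UDATrainConfig",
    "DomainHead",
    "lambda_schedule",
    "uda_train",
    "convergence_report",
]

LAMBDA_MAX = 2.0 / (1.0 + math.exp(-5.0)) - 1.0


@dataclass(frozen=True)
class UDATrainConfig:
    batch_size: int = 4
    lr: float = 1e-5
    epochs: int = 200
    weight_decay: float = 1e-3
    alpha: float = 0.1
    domain_hidden: int = 256
    seed: int = 0

    def __post_init__(self):
        for name in ("batch_size", "lr", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def lambda_schedule(i: int, epoch: int, n_iter: int, n_epoch: int) -> float:
    """Adversarial weight at iteration ``i`` of ``epoch``; monotone in progress."""
    if n_iter <= 0 or n_epoch <= 0:
        raise ValueError("n_iter and n_epoch must be positive")
    p = (i + epoch * n_iter) / (n_epoch * n_iter)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"training progress p={p} outside [0, 1]")
    return 2.0 / (1.0 + math.exp(-5.0 * p)) - 1.0


class DomainHead(nn.Module):
    """GRL -> hidden rectified layer -> two-way domain softmax."""

    def __init__(self, n_features: int, hidden: int, rng: np.random.Generator):
        self.grl = nn.GradientReversal(0.0)
        self.net = nn.Sequential(
            nn.Linear(n_features, hidden, rng=rng),
            nn.ReLU(),
            nn.Linear(hidden, 2, rng=rng),
        )

    def parameters(self) -> list[nn.Param]:
        return self.net.parameters()

    def modules(self):
        yield self
        yield self.grl
        yield from self.net.modules()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(self.grl.forward(x, train=train), train=train)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return self.grl.backward(self.net.backward(gout))


def uda_train(
    model: DenseNet3D,
    x_source: np.ndarray,
    y_source: np.ndarray,
    x_target: np.ndarray,
    config: UDATrainConfig = UDATrainConfig(),
) -> tuple[DenseNet3D, DomainHead, pd.DataFrame]:
    """Adapt a (typically source-pretrained) model with unlabeled target data.

    Returns the adapted model, the domain head, and per-iteration loss traces
    (classification, source/target domain losses, lambda, weighted total).
    """
    if x_target.shape[0] == 0:
        raise ValueError("target set is empty")
    rng = np.random.default_rng(config.seed)
    head_d = DomainHead(model.n_features, config.domain_hidden, rng)
    params = model.parameters() + head_d.parameters()
    opt = nn.Adam(params, lr=config.lr, weight_decay=config.weight_decay)
    n_s, n_t = x_source.shape[0], x_target.shape[0]
    bs = config.batch_size
    n_iter = min(n_s, n_t) // bs
    if n_iter == 0:
        raise ValueError("batch size exceeds the smaller domain")
    rows = []
    for epoch in range(config.epochs):
        src_order = rng.permutation(n_s)
        tgt_order = rng.permutation(n_t)
        for it in range(n_iter):
            lam = lambda_schedule(it, epoch, n_iter, config.epochs)
            head_d.grl.lam = lam
            src = src_order[it * bs : (it + 1) * bs]
            tgt = tgt_order[it * bs : (it + 1) * bs]
            opt.zero_grad()

            # source pass: classification + domain(source, label 0)
            feats = model.features(x_source[src], train=True)
            logits_c = model.head.forward(feats, train=True)
            loss_cls, g_cls = nn.cross_entropy(logits_c, y_source[src])
            logits_ds = head_d.forward(feats, train=True)
            loss_ds, g_ds = nn.cross_entropy(logits_ds, np.zeros(bs, dtype=int))
            g_feat = model.head.backward(g_cls)
            if config.alpha > 0:
                g_feat = g_feat + head_d.backward(config.alpha * g_ds)
            model.trunk.backward(g_feat)

            # target pass: domain only (label 1); target class labels unused
            feats_t = model.features(x_target[tgt], train=True)
            logits_dt = head_d.forward(feats_t, train=True)
            loss_dt, g_dt = nn.cross_entropy(logits_dt, np.ones(bs, dtype=int))
            if config.alpha > 0:
                model.trunk.backward(head_d.backward(config.alpha * g_dt))

            opt.step()
            total = loss_cls + config.alpha * (loss_ds + loss_dt)
            if not np.isfinite(total):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            rows.append(
                {
                    "epoch": epoch,
                    "iter": it,
                    "lambda": lam,
                    "loss_cls_source": loss_cls,
                    "loss_dom_source": loss_ds,
                    "loss_dom_target": loss_dt,
                    "loss_total": total,
                }
            )
    return model, head_d, pd.DataFrame(rows)


def convergence_report(
    traces: pd.DataFrame,
    window: int = 10,
    sd_tol: float = 0.05,
    gap_tol: float = 0.2,
) -> dict:
    """Adversarial-convergence diagnostics from per-iteration loss traces.

    Computes, over the last ``window`` epochs, the rolling standard deviation
    of the per-epoch mean source and target domain losses and their final
    absolute gap; training is flagged converged when the oscillation
    amplitudes and the gap all fall below their tolerances.
    """
    per_epoch = traces.groupby("epoch")[
        ["loss_dom_source", "loss_dom_target"]
    ].mean()
    if len(per_epoch) < 2 * window:
        raise ValueError(f"need >= {2 * window} epochs of traces")
    tail = per_epoch.iloc[-window:]
    sd_src = float(tail["loss_dom_source"].std(ddof=0))
    sd_tgt = float(tail["loss_dom_target"].std(ddof=0))
    gap = float(
        abs(tail["loss_dom_source"].mean() - tail["loss_dom_target"].mean())
    )
    return {
        "rolling_sd_source": sd_src,
        "rolling_sd_target": sd_tgt,
        "domain_loss_gap": gap,
        "converged": bool(sd_src < sd_tol and sd_tgt < sd_tol and gap < gap_tol),
    }
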