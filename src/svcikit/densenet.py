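"""3D densely-connected classifier for diffusion scalar-map combinations.

The network follows the densely-connected design: a convolutional stem, four
dense blocks (one dense layer each) interleaved with three transition layers
(convolution + stride-2 average pooling), a global average pooling layer, and
a dropout-regularized fully connected head ending in a two-way softmax that
outputs the SVCI probability.  A dense layer is two convolutions — a 1x1x1
bottleneck followed by a 3x3x3 convolution producing ``growth`` feature maps —
each preceded by batch normalization and a rectifier; its output is channel-
concatenated with its input, so every layer sees all earlier feature maps of
its block.

Defaults reproduce the reference recipe (64 stem filters, growth 32, batch 16,
lr 5e-5, 50 epochs, Adam with weight decay 1e-3, cosine-annealed learning
rate, dropout 0.5).  ``init_filters``/``growth`` are configurable so that the
same architecture family runs at desk scale on a single CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import nn

__all__ = [
    "DenseNetConfig",
    "TrainConfig",
    "DenseNet3D",
    "build_model",
    "augment",
    "split_and_cv",
    "train",
    "predict_proba",
]


@dataclass(frozen=True)
class DenseNetConfig:
    in_channels: int = 2
    n_classes: int = 2
    init_filters: int = 64
    growth: int = 32
    n_blocks: int = 4
    dropout: float = 0.5

    def __post_init__(self):
        if not 1 <= self.in_channels <= 4:
            raise ValueError("in_channels must be in 1..4")
        if self.n_blocks != 4:
            raise ValueError("the architecture fixes 4 dense blocks")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    lr: float = 5e-5
    epochs: int = 50
    weight_decay: float = 1e-3
    augment: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("batch_size", "lr", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _dense_layer(c_in: int, growth: int, rng: np.random.Generator) -> nn.Module:
    return nn.Concat(
        nn.Sequential(
            nn.BatchNorm(c_in),
            nn.ReLU(),
            nn.Conv3d(c_in, 4 * growth, kernel=1, rng=rng),
            nn.BatchNorm(4 * growth),
            nn.ReLU(),
            nn.Conv3d(4 * growth, growth, kernel=3, rng=rng),
        )
    )


def _transition(c: int, rng: np.random.Generator) -> nn.Module:
    return nn.Sequential(
        nn.BatchNorm(c),
        nn.ReLU(),
        nn.Conv3d(c, c, kernel=1, rng=rng),
        nn.AvgPool3d(),
    )


class DenseNet3D(nn.Module):
    """Trunk (feature extractor ``F``) + classifier head (``C``).

    The trunk ends at global average pooling; the head is dropout followed by
    a fully connected layer producing two logits.  Keeping the two exposed
    separately lets the domain-adversarial branch tap pooled features.
    """

    def __init__(self, config: DenseNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.init_filters
        layers: list[nn.Module] = [nn.Conv3d(config.in_channels, c, kernel=3, rng=rng)]
        for b in range(config.n_blocks):
            layers.append(_dense_layer(c, config.growth, rng))
            c += config.growth
            if b < config.n_blocks - 1:
                layers.append(_transition(c, rng))
        layers.append(nn.GlobalAvgPool())
        self.trunk = nn.Sequential(*layers)
        self.head = nn.Sequential(
            nn.Dropout(config.dropout, rng=rng),
            nn.Linear(c, config.n_classes, rng=rng),
        )
        self.n_features = c

    def parameters(self) -> list[nn.Param]:
        return self.trunk.parameters() + self.head.parameters()

    def modules(self):
        yield self
        yield from self.trunk.modules()
        yield from self.head.modules()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a channels-first batch ``(N, C, X, Y, Z)``."""
        self._check_input(x)
        feats = self.trunk.forward(np.moveaxis(x, 1, -1).astype(np.float32), train=train)
        return self.head.forward(feats, train=train)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.head.backward(gout)
        g = self.trunk.backward(g)
        return np.moveaxis(g, -1, 1)

    def features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._check_input(x)
        return self.trunk.forward(np.moveaxis(x, 1, -1).astype(np.float32), train=train)

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def checksum(self) -> float:
        """Deterministic scalar summary of all parameters (init/repro checks)."""
        return float(sum(np.abs(p.value).sum() for p in self.parameters()))

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 5 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (N, {self.config.in_channels}, X, Y, Z) input, got {x.shape}"
            )
        if min(x.shape[2:]) < 16:
            raise ValueError("each spatial dimension must be >= 16 (three stride-2 pools)")
        for s in x.shape[2:]:
            if s % 8 != 0:
                raise ValueError("spatial dimensions must be divisible by 8")


def build_model(config: DenseNetConfig, seed: int = 0) -> DenseNet3D:
    return DenseNet3D(config, seed=seed)


def augment(
    sample: np.ndarray,
    rng: np.random.Generator,
    p_intensity: float = 0.30,
    p_spatial: float = 0.20,
) -> np.ndarray:
    """On-the-fly augmentation of one channels-first volume ``(C, X, Y, Z)``.

    With probability ``p_intensity`` apply one of {additive intensity shift by
    ``f - 1`` with ``f ~ U(0.9, 1.1)``, intensity scaling by 1.1}; with
    probability ``p_spatial`` apply one of {flip along the first spatial axis,
    zoom by ``U(0.9, 1.1)`` resampled back onto the grid}.  Applied to
    training batches only, never to validation or test data.
    """
    out = sample
    if rng.random() < p_intensity:
        if rng.random() < 0.5:
            out = out + (rng.uniform(0.9, 1.1) - 1.0)
        else:
            out = out * 1.1
    if rng.random() < p_spatial:
        if rng.random() < 0.5:
            out = out[:, ::-1, :, :].copy()
        else:
            f = rng.uniform(0.9, 1.1)
            zoomed = np.stack(
                [ndimage.zoom(ch, f, order=1, mode="nearest") for ch in out]
            )
            out = _fit_to(zoomed, sample.shape)
    return np.ascontiguousarray(out, dtype=np.float32)


def _fit_to(vol: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Center-crop or zero-pad the spatial axes of ``vol`` to ``shape``."""
    out = np.zeros(shape, dtype=vol.dtype)
    src, dst = [slice(None)], [slice(None)]
    for axis in range(1, 4):
        n_in, n_out = vol.shape[axis], shape[axis]
        if n_in >= n_out:
            a = (n_in - n_out) // 2
            src.append(slice(a, a + n_out))
            dst.append(slice(None))
        else:
            a = (n_out - n_in) // 2
            src.append(slice(None))
            dst.append(slice(a, a + n_in))
    out[tuple(dst)] = vol[tuple(src)]
    return out


def split_and_cv(
    labels: np.ndarray,
    seed: int = 0,
    test_fraction: float = 0.2,
    n_folds: int = 5,
) -> dict:
    """Stratified 80/20 train/test split plus stratified K folds of the train set.

    Returns ``{"train": idx, "test": idx, "folds": [(fit_idx, val_idx), ...]}``
    with all indices referring to the original array.  After cross-validation
    the model is meant to be retrained on the full training set.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    if counts.min() < n_folds:
        raise ValueError(f"each class needs >= {n_folds} members for stratification")
    idx = np.arange(len(labels))
    tr, te = train_test_split(
        idx, test_size=test_fraction, stratify=labels, random_state=seed
    )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [(tr[a], tr[b]) for a, b in skf.split(tr, labels[tr])]
    return {"train": np.sort(tr), "test": np.sort(te), "folds": folds}


def train(
    model: DenseNet3D,
    x: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
) -> list[dict]:
    """Train with cross-entropy, Adam, and a cosine-annealed learning rate.

    ``x`` is a normalized channels-first batch, ``y`` integer labels
    (1 = SVCI).  Returns a per-epoch history of mean loss and learning rate.
    """
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    n = x.shape[0]
    history: list[dict] = []
    for epoch in range(config.epochs):
        lr = nn.cosine_lr(config.lr, epoch, config.epochs)
        opt.lr = lr
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            xb = x[sel]
            if config.augment:
                xb = np.stack([augment(s, rng) for s in xb])
            opt.zero_grad()
            logits = model.forward(xb, train=True)
            loss, grad = nn.cross_entropy(logits, y[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            model.backward(grad)
            opt.step()
            losses.append(loss)
        history.append({"epoch": epoch, "loss": float(np.mean(losses)), "lr": lr})
    return history


def predict_proba(model: DenseNet3D, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """SVCI probability (positive-class softmax output) per subject."""
    probs = []
    for start in range(0, x.shape[0], batch_size):
        logits = model.forward(x[start : start + batch_size], train=False)
        probs.append(nn.softmax(logits)[:, 1])
    return np.concatenate(probs)
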