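"""The 3D patch classifier: architecture, balanced loss, training, scoring.

Architecture: four convolution blocks, each two 3x3x3 convolutions with
ReLU + batch normalization followed by 2x2x2 max pooling, then two dense
layers with ReLU and 0.5 dropout, and a single sigmoid output. The loss is
balanced cross-entropy, weighting each class inversely to its frequency so
the rare positive (TZ-containing) patches are not drowned out. Early
stopping monitors validation AUROC.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .evaluate import auroc_score

__all__ = [
    "CNNConfig",
    "TrainConfig",
    "TrainedModel",
    "build_cnn",
    "balanced_cross_entropy",
    "default_class_weights",
    "train_classifier",
    "score_patches",
    "save_model",
    "load_model",
]

_EPS = 1e-7


@dataclass(frozen=True)
class CNNConfig:
    n_blocks: int = 4
    convs_per_block: int = 2
    kernel: int = 3
    pool: int = 2
    dense_units: tuple[int, int] = (256, 64)
    dropout: float = 0.5
    base_channels: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_blocks < 1 or self.convs_per_block < 1:
            raise ValueError("need at least one block and one conv per block")

    def channels(self) -> list[int]:
        return [self.base_channels * 2 ** i for i in range(self.n_blocks)]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    max_epochs: int = 50
    patience: int = 5
    batch_size: int = 16
    seed: int = 0
    class_weights: tuple[float, float] | None = None  # (w_pos, w_neg); None -> balanced

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience cannot exceed max_epochs")


class _Network:
    """The layer stack with a fused sigmoid/balanced-BCE training step."""

    def __init__(self, config: CNNConfig, patch_side: int, seed: int):
        reduction = config.pool ** config.n_blocks
        if patch_side % reduction != 0:
            raise ValueError(
                f"patch_side={patch_side} must be divisible by pool^n_blocks={reduction} "
                f"so that {config.n_blocks} pooling stages land on an integer grid"
            )
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x1217])
        layers: list[tuple[str, nn.Layer]] = []
        in_c = 1
        for b, out_c in enumerate(config.channels()):
            for c in range(config.convs_per_block):
                layers.append((f"block{b}_conv{c}", nn.Conv3D(in_c, out_c, config.kernel, rng)))
                layers.append((f"block{b}_relu{c}", nn.ReLU()))
                layers.append((f"block{b}_bn{c}", nn.BatchNorm3D(out_c)))
                in_c = out_c
            layers.append((f"block{b}_pool", nn.MaxPool3D(config.pool)))
        layers.append(("flatten", nn.Flatten()))
        side = patch_side // reduction
        features = in_c * side ** 3
        for d, units in enumerate(config.dense_units):
            layers.append((f"dense{d}", nn.Dense(features, units, rng)))
            layers.append((f"dense{d}_relu", nn.ReLU()))
            layers.append((f"dense{d}_dropout", nn.Dropout(config.dropout)))
            features = units
        layers.append(("output", nn.Dense(features, 1, rng)))
        self.layers = layers
        self.config = config
        self.patch_side = patch_side

    def logits(self, x: np.ndarray, train: bool, rng=None) -> np.ndarray:
        out = x
        for _, layer in self.layers:
            out = layer.forward(out, train, rng)
        return out[:, 0]

    def backward(self, dlogit: np.ndarray) -> None:
        grad = dlogit[:, None]
        for _, layer in reversed(self.layers):
            grad = layer.backward(grad)

    def scores(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = np.empty(x.shape[0])
        for start in range(0, x.shape[0], batch_size):
            z = self.logits(x[start : start + batch_size], train=False)
            out[start : start + batch_size] = 1.0 / (1.0 + np.exp(-z))
        return out

    def get_state(self) -> list[dict]:
        state = []
        for _, layer in self.layers:
            entry = {k: v.copy() for k, v in layer.params.items()}
            if isinstance(layer, nn.BatchNorm3D):
                entry["running_mean"] = layer.running_mean.copy()
                entry["running_var"] = layer.running_var.copy()
            state.append(entry)
        return state

    def set_state(self, state: list[dict]) -> None:
        for (_, layer), entry in zip(self.layers, state):
            for k in layer.params:
                layer.params[k] = entry[k].copy()
            if isinstance(layer, nn.BatchNorm3D):
                layer.running_mean = entry["running_mean"].copy()
                layer.running_var = entry["running_var"].copy()


@dataclass
class TrainedModel:
    network: _Network
    cnn_config: CNNConfig
    train_config: TrainConfig | None = None
    history: list[dict] = field(default_factory=list)


def build_cnn(config: CNNConfig, patch_side: int, seed: int = 0) -> TrainedModel:
    """Construct the (untrained) classifier for patches of side ``patch_side``."""
    return TrainedModel(network=_Network(config, patch_side, seed), cnn_config=config)


def balanced_cross_entropy(scores, labels, w_pos: float = 1.0, w_neg: float = 1.0) -> float:
    """``-mean(w_pos * y * log p + w_neg * (1-y) * log(1-p))``."""
    if w_pos <= 0 or w_neg <= 0:
        raise ValueError("class weights must be positive")
    p = np.clip(np.asarray(scores, dtype=float), _EPS, 1.0 - _EPS)
    y = np.asarray(labels, dtype=float)
    return float(-np.mean(w_pos * y * np.log(p) + w_neg * (1.0 - y) * np.log(1.0 - p)))


def default_class_weights(labels) -> tuple[float, float]:
    """Balanced weights ``w_pos = N / (2 N+)``, ``w_neg = N / (2 N-)``."""
    y = np.asarray(labels)
    n = y.size
    n_pos = int(y.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("default class weights need both classes present")
    return n / (2.0 * n_pos), n / (2.0 * n_neg)


def _as_batch(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 4:
        x = x[:, None]
    if x.ndim != 5 or x.shape[1] != 1:
        raise ValueError("patches must have shape (N, side, side, side)")
    return x


def train_classifier(
    x_train,
    y_train,
    x_val,
    y_val,
    train_config: TrainConfig,
    cnn_config: CNNConfig,
    augment_fn=None,
) -> TrainedModel:
    """Train the patch classifier with early stopping on validation AUROC.

    ``augment_fn``, when given, is called once per epoch with an rng and
    must return replacement arrays for the positive training patches (same
    order as ``y_train == 1``) — this is how per-epoch translation/zoom
    augmentation of positives is wired in without coupling the trainer to
    volume storage.
    """
    x_train = _as_batch(x_train)
    x_val = _as_batch(x_val)
    y_train = np.asarray(y_train, dtype=np.float32)
    y_val = np.asarray(y_val, dtype=np.float32)
    for name, y in (("training", y_train), ("validation", y_val)):
        if y.min() == y.max():
            raise ValueError(f"{name} split must contain both classes")

    if train_config.class_weights is None:
        w_pos, w_neg = default_class_weights(y_train)
    else:
        w_pos, w_neg = train_config.class_weights

    net = _Network(cnn_config, x_train.shape[-1], train_config.seed)
    optimizer = nn.Adam([l for _, l in net.layers], learning_rate=train_config.learning_rate)
    rng = np.random.default_rng([train_config.seed & 0x7FFFFFFF, 0x7E41])
    pos_idx = np.flatnonzero(y_train == 1)

    history: list[dict] = []
    best_state = net.get_state()
    best_auroc = -np.inf
    since_best = 0
    n = x_train.shape[0]
    for epoch in range(train_config.max_epochs):
        if augment_fn is not None and pos_idx.size:
            x_train[pos_idx] = _as_batch(augment_fn(rng))
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            z = net.logits(xb, train=True, rng=rng)
            p = 1.0 / (1.0 + np.exp(-z))
            pc = np.clip(p, _EPS, 1.0 - _EPS)
            loss = -np.mean(w_pos * yb * np.log(pc) + w_neg * (1 - yb) * np.log(1 - pc))
            # fused d(loss)/d(logit) for sigmoid + weighted BCE
            dz = (w_pos * yb * (p - 1.0) + w_neg * (1.0 - yb) * p) / idx.size
            net.backward(dz.astype(np.float32))
            optimizer.step()
            losses.append(loss)
        val_auroc = auroc_score(net.scores(x_val), y_val)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_auroc": float(val_auroc)}
        )
        if val_auroc > best_auroc:
            best_auroc = val_auroc
            best_state = net.get_state()
            since_best = 0
        else:
            since_best += 1
        if since_best >= train_config.patience:
            break
    net.set_state(best_state)
    return TrainedModel(
        network=net, cnn_config=cnn_config, train_config=train_config, history=history
    )


def save_model(model: TrainedModel, directory) -> None:
    """Persist weights (npz), config snapshot (JSON), and history (CSV)."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, entry in enumerate(model.network.get_state()):
        for key, value in entry.items():
            arrays[f"{i}__{key}"] = value
    np.savez(directory / "weights.npz", **arrays)
    meta = {
        "cnn_config": {
            **{k: v for k, v in vars(model.cnn_config).items() if k != "dense_units"},
            "dense_units": list(model.cnn_config.dense_units),
        },
        "patch_side": model.network.patch_side,
        "extra": dict(getattr(model, "_extra", {}) or {}),
    }
    (directory / "config.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    with open(directory / "history.csv", "w") as fh:
        fh.write("epoch,train_loss,val_auroc\n")
        for h in model.history:
            fh.write(f"{h['epoch']},{h['train_loss']},{h['val_auroc']}\n")


def load_model(directory) -> TrainedModel:
    import json
    from pathlib import Path

    directory = Path(directory)
    meta = json.loads((directory / "config.json").read_text())
    cfg = dict(meta["cnn_config"])
    cfg["dense_units"] = tuple(cfg["dense_units"])
    cnn_config = CNNConfig(**cfg)
    net = _Network(cnn_config, int(meta["patch_side"]), seed=0)
    data = np.load(directory / "weights.npz")
    state: list[dict] = [{} for _ in net.layers]
    for name in data.files:
        i, key = name.split("__", 1)
        state[int(i)][key] = data[name]
    net.set_state(state)
    model = TrainedModel(network=net, cnn_config=cnn_config)
    model._extra = meta.get("extra", {})
    return model


def score_patches(model: TrainedModel, patches, k: int | None = None) -> np.ndarray:
    """Score a scan's patches; returns one value in [0, 1] per patch, in
    grid order. With ``k`` given, enforces the k^3 patch count."""
    x = _as_batch(patches)
    if k is not None and x.shape[0] != k ** 3:
        raise ValueError(f"expected {k ** 3} patches, got {x.shape[0]}")
    return model.network.scores(x)
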