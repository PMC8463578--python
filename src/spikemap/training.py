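"""Training and conversion.

Two routes to an explainable spiking network:

1. surrogate-gradient training from scratch — backpropagation through time
   with a triangular pseudo-derivative at the spike nonlinearity and
   per-time-step batch normalization, minimizing cross-entropy on the
   accumulated output potentials;
2. ANN-SNN conversion — copy a trained ReLU network's weights and set each
   layer's firing threshold, in order from shallow to deep, to the maximum
   drive observed while running rate-coded calibration inputs through the
   partially converted network.

Also trains the reference ReLU network itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ann import ReLUConvNet
from .encoding import poisson_encode_batch
from .snn_core import (
    INF_THRESHOLD,
    LayerSpec,
    NetworkConfig,
    NeuronParams,
    SpikingNetwork,
)
from .synthetic_data import ShapeDataset

__all__ = [
    "TrainConfig",
    "ConversionReport",
    "snn_loss",
    "train_snn",
    "train_ann",
    "convert_ann_to_snn",
    "snn_predict",
]


@dataclass
class TrainConfig:
    epochs: int = 15
    batch_size: int = 32
    lr: float = 0.1
    lr_decay: float = 0.1
    lr_milestones: tuple[float, ...] = (0.5, 0.7, 0.9)  # fractions of epochs
    momentum: float = 0.9
    weight_decay: float = 5e-4
    timesteps: int = 20
    leak: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.timesteps) < 0:
            raise ValueError("config values must be non-negative")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (batch statistics)")

    def lr_at(self, epoch: int) -> float:
        lr = self.lr
        for m in self.lr_milestones:
            if epoch >= m * self.epochs:
                lr *= self.lr_decay
        return lr


def _log_softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def snn_loss(output_potentials: np.ndarray, label: int | np.ndarray, num_classes: int) -> float:
    """Cross-entropy of the softmax over accumulated output potentials."""
    u = np.asarray(output_potentials, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite output potentials")
    single = u.ndim == 1
    if single:
        u = u[None]
    labels = np.atleast_1d(label)
    if u.shape[1] != num_classes:
        raise ValueError("potential vector length != num_classes")
    if labels.min() < 0 or labels.max() >= num_classes:
        raise ValueError("label out of range")
    lsm = _log_softmax(u)
    return float(-lsm[np.arange(len(labels)), labels].mean())


class _SGD:
    """SGD with momentum and decoupled-from-nothing classic weight decay."""

    def __init__(self, params: dict[str, np.ndarray], cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.velocity = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray], lr: float, decay_keys=()):
        for k, g in grads.items():
            if self.cfg.weight_decay and k in decay_keys:
                g = g + self.cfg.weight_decay * self.params[k]
            v = self.velocity[k]
            v *= self.cfg.momentum
            v += g
            self.params[k] -= lr * v


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for s in range(0, n, batch_size):
        chunk = order[s : s + batch_size]
        if len(chunk) >= 2:
            yield chunk


def train_snn(
    dataset: ShapeDataset,
    config: NetworkConfig,
    cfg: TrainConfig,
) -> tuple[SpikingNetwork, list[dict]]:
    """Surrogate-gradient BPTT training.  Returns the trained network and a
    per-epoch history of loss and training accuracy.  Fully seeded."""
    rng = np.random.default_rng(cfg.seed)
    net = SpikingNetwork(config, rng=np.random.default_rng(rng.integers(2**31)))
    train = dataset.subset("train")
    images, labels = train.images, train.labels
    n = len(labels)
    params = dict(net.weights)
    scale_keys = {}
    for i, p in net.bntt.items():
        params[f"bntt{i}.scale"] = p.scale
        scale_keys[f"bntt{i}.scale"] = i
    opt = _SGD(params, cfg)
    history: list[dict] = []
    C = config.num_classes
    for epoch in range(cfg.epochs):
        lr = cfg.lr_at(epoch)
        tot_loss, tot_correct, tot_seen = 0.0, 0, 0
        for idx in _batches(n, cfg.batch_size, rng):
            raster = poisson_encode_batch(
                images[idx], config.total_timesteps, np.random.default_rng(rng.integers(2**31))
            )
            out = net.forward(raster, mode="train", keep_cache=True)
            u = out["potentials"]
            if not np.all(np.isfinite(u)):
                raise FloatingPointError("training diverged: non-finite potentials")
            lsm = _log_softmax(u)
            b = len(idx)
            loss = -lsm[np.arange(b), labels[idx]].mean()
            probs = np.exp(lsm)
            seed = probs.copy()
            seed[np.arange(b), labels[idx]] -= 1.0
            seed /= b
            grads = net.backward(out["cache"], seed, bn_batch_stats=True)
            gd = dict(grads["weights"])
            for key, li in scale_keys.items():
                gd[key] = grads["bntt_scale"][li]
            opt.step(gd, lr, decay_keys=net.weights.keys())
            tot_loss += loss * b
            tot_correct += int((u.argmax(axis=1) == labels[idx]).sum())
            tot_seen += b
        history.append(
            {
                "epoch": epoch,
                "loss": tot_loss / max(tot_seen, 1),
                "accuracy": tot_correct / max(tot_seen, 1),
                "lr": lr,
            }
        )
    return net, history


def train_ann(
    dataset: ShapeDataset,
    config: NetworkConfig,
    cfg: TrainConfig,
) -> tuple[ReLUConvNet, list[dict]]:
    """Standard SGD training of the reference ReLU network."""
    rng = np.random.default_rng(cfg.seed)
    ann = ReLUConvNet(config, rng=np.random.default_rng(rng.integers(2**31)))
    train = dataset.subset("train")
    images = train.images / 255.0
    labels = train.labels
    n = len(labels)
    opt = _SGD(ann.weights, cfg)
    history: list[dict] = []
    for epoch in range(cfg.epochs):
        lr = cfg.lr_at(epoch)
        tot_loss, tot_correct, tot_seen = 0.0, 0, 0
        for idx in _batches(n, cfg.batch_size, rng):
            out = ann.forward(images[idx], keep_cache=True)
            logits = out["logits"]
            lsm = _log_softmax(logits)
            b = len(idx)
            loss = -lsm[np.arange(b), labels[idx]].mean()
            if not np.isfinite(loss):
                raise FloatingPointError("training diverged")
            seed = np.exp(lsm)
            seed[np.arange(b), labels[idx]] -= 1.0
            seed /= b
            grads = ann.backward(out["cache"], seed)
            opt.step(grads["weights"], lr, decay_keys=ann.weights.keys())
            tot_loss += loss * b
            tot_correct += int((logits.argmax(axis=1) == labels[idx]).sum())
            tot_seen += b
        history.append(
            {
                "epoch": epoch,
                "loss": tot_loss / max(tot_seen, 1),
                "accuracy": tot_correct / max(tot_seen, 1),
                "lr": lr,
            }
        )
    return ann, history


@dataclass
class ConversionReport:
    thresholds: dict[int, float]  # conv layer index -> firing threshold
    ann_max_activation: dict[int, float]
    rate_activation_corr: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(th <= 0 for th in self.thresholds.values()):
            raise ValueError("all conversion thresholds must be positive")


def convert_ann_to_snn(
    ann: ReLUConvNet,
    calibration_images: np.ndarray,
    timesteps: int = 128,
    leak: float = 1.0,
    seed: int = 0,
) -> tuple[SpikingNetwork, ConversionReport]:
    """Threshold-normalization conversion.

    Weights are copied; then, layer by layer from the input side, the
    calibration set is rate-coded and run through the partially converted
    network for all T steps, and the layer's threshold is set to the
    maximum drive observed over all steps, positions and samples.
    """
    calibration_images = np.asarray(calibration_images, dtype=float)
    if calibration_images.ndim != 4 or len(calibration_images) == 0:
        raise ValueError("calibration set must be non-empty [B,C,H,W]")
    base = ann.config
    layers = tuple(
        LayerSpec(
            s.kind,
            s.out_channels,
            s.kernel_size,
            NeuronParams(leak=1.0, threshold=INF_THRESHOLD)
            if s.kind == "linear"
            else NeuronParams(leak=leak, threshold=1.0),
            bntt=False,
        )
        for s in base.layers
    )
    config = NetworkConfig(layers, timesteps, base.num_classes, base.input_shape)
    net = SpikingNetwork(config)
    net.weights = {k: v.copy() for k, v in ann.weights.items()}
    net.bntt = {}

    raster = poisson_encode_batch(calibration_images, timesteps, seed)
    thresholds: dict[int, float] = {}
    for li in config.conv_indices:
        observed = {"max": -np.inf}

        def hook(i, t, drive, _li=li, _obs=observed):
            if i == _li:
                _obs["max"] = max(_obs["max"], float(drive.max()))

        net.forward(raster, drive_hook=hook)
        if not (observed["max"] > 0):
            raise ValueError(f"layer {li}: no positive drive observed during calibration")
        thresholds[li] = observed["max"]
        net.config = _with_threshold(net.config, li, observed["max"], leak)

    # diagnostics: ANN activation maxima and rate/activation correlation
    ann_out = ann.forward(calibration_images / 255.0)
    ann_max = {i: float(a.max()) for i, a in ann_out["activations"].items()}
    corr: dict[int, float] = {}
    rec = net.forward(raster, record_layers=config.conv_indices)
    for i in config.conv_indices:
        rates = rec["records"][i].mean(axis=0).ravel()
        acts = ann_out["activations"][i].ravel()
        if rates.std() > 0 and acts.std() > 0:
            corr[i] = float(np.corrcoef(rates, acts)[0, 1])
        else:
            corr[i] = 0.0
    report = ConversionReport(thresholds, ann_max, corr)
    return net, report


def _with_threshold(
    config: NetworkConfig, layer_index: int, threshold: float, leak: float
) -> NetworkConfig:
    layers = list(config.layers)
    s = layers[layer_index]
    layers[layer_index] = LayerSpec(
        s.kind, s.out_channels, s.kernel_size, NeuronParams(leak=leak, threshold=threshold), s.bntt
    )
    return NetworkConfig(
        tuple(layers), config.total_timesteps, config.num_classes, config.input_shape
    )


def snn_predict(
    net: SpikingNetwork,
    images: np.ndarray,
    seed: int = 0,
    batch_size: int = 64,
) -> np.ndarray:
    """Rate-code images, run the network, return argmax classes."""
    images = np.asarray(images, dtype=float)
    T = net.config.total_timesteps
    rng = np.random.default_rng(seed)
    preds = []
    for s in range(0, len(images), batch_size):
        raster = poisson_encode_batch(images[s : s + batch_size], T, rng)
        out = net.forward(raster)
        preds.append(out["potentials"].argmax(axis=1))
    return np.concatenate(preds)
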