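"""Discrete-time leaky integrate-and-fire (LIF) network simulation.

A network is a stack of convolutional spiking layers (optionally normalized
per time-step), average-pooling stages, a global-average-pool, and a final
linear accumulator whose membrane potentials are the class logits.

Update rule per neuron and step (soft reset, one-pass):

    u_t   = leak * u_{t-1} + drive_t - threshold * o_{t-1}
    o_t   = 1  if u_t > threshold else 0

The output layer uses ``leak=1`` and an infinite threshold so it never fires
and its potential after T steps is the summed drive (the logits).

Conventions: spike rasters are indexed ``[time, batch, channel, row, col]``
(batch axis dropped in the single-sample public API), 0-based, row-major.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _layers

__all__ = [
    "INF_THRESHOLD",
    "NeuronParams",
    "NeuronState",
    "BNTTParams",
    "LayerSpec",
    "NetworkConfig",
    "LayerRecord",
    "SpikingNetwork",
    "lif_update",
    "bntt_normalize",
    "forward_network",
]

#: Sentinel threshold for non-firing accumulator layers.
INF_THRESHOLD = math.inf


@dataclass(frozen=True)
class NeuronParams:
    """Leak factor and firing threshold of an LIF layer."""

    leak: float = 0.99
    threshold: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.leak <= 1.0):
            raise ValueError(f"leak must be in [0,1], got {self.leak}")
        if not (self.threshold > 0.0):
            raise ValueError(f"threshold must be > 0, got {self.threshold}")


@dataclass
class NeuronState:
    """Membrane potentials and previous-step spikes for one layer."""

    potential: np.ndarray
    last_spike: np.ndarray

    def __post_init__(self) -> None:
        if self.potential.shape != self.last_spike.shape:
            raise ValueError("potential and last_spike shapes differ")

    @classmethod
    def zeros(cls, shape: tuple[int, ...]) -> "NeuronState":
        return cls(np.zeros(shape), np.zeros(shape))


def lif_update(
    state: NeuronState, weighted_input: np.ndarray, params: NeuronParams
) -> tuple[NeuronState, np.ndarray]:
    """One LIF step: integrate, fire, schedule soft reset for the next step.

    Returns the new state and the binary spike array.  The reset term uses
    the *previous* step's spikes, so a spike never suppresses the potential
    that caused it.
    """
    weighted_input = np.asarray(weighted_input, dtype=float)
    if weighted_input.shape != state.potential.shape:
        raise ValueError(
            f"shape mismatch: state {state.potential.shape} vs "
            f"input {weighted_input.shape}"
        )
    if not np.all(np.isfinite(weighted_input)):
        raise ValueError("non-finite weighted input")
    if math.isinf(params.threshold):
        u = params.leak * state.potential + weighted_input
        spikes = np.zeros_like(u)
    else:
        u = (
            params.leak * state.potential
            + weighted_input
            - params.threshold * state.last_spike
        )
        spikes = (u > params.threshold).astype(float)
    return NeuronState(u, spikes), spikes


@dataclass
class BNTTParams:
    """Per-channel, per-time-step normalization: scale * (x - mean)/std.

    One (scale, running_mean, running_var) triplet per (time-step, channel);
    there is no additive shift term.
    """

    scale: np.ndarray  # [T, C]
    running_mean: np.ndarray  # [T, C]
    running_var: np.ndarray  # [T, C]
    eps: float = 1e-5
    momentum: float = 0.1

    @classmethod
    def init(cls, timesteps: int, channels: int, eps: float = 1e-5) -> "BNTTParams":
        return cls(
            scale=np.ones((timesteps, channels)),
            running_mean=np.zeros((timesteps, channels)),
            running_var=np.ones((timesteps, channels)),
            eps=eps,
        )

    def validate(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if np.any(self.running_var < 0):
            raise ValueError("running_var must be non-negative")


def bntt_normalize(
    preactivation: np.ndarray,
    params: BNTTParams,
    t: int,
    mode: str = "eval",
) -> np.ndarray:
    """Normalize a [B,C,...] drive with the statistics of time-step ``t``.

    ``train`` mode uses mini-batch statistics (over batch and spatial axes)
    and updates the running statistics by exponential moving average;
    ``eval`` mode applies the stored running statistics.
    """
    params.validate()
    T = params.scale.shape[0]
    if not (0 <= t < T):
        raise IndexError(f"time-step {t} outside [0,{T})")
    x = np.asarray(preactivation, dtype=float)
    c = x.shape[1]
    axes = (0,) + tuple(range(2, x.ndim))
    bshape = (1, c) + (1,) * (x.ndim - 2)
    if mode == "train":
        if x.shape[0] < 2:
            raise ValueError("train-mode normalization needs batch size >= 2")
        mean = x.mean(axis=axes)
        var = x.var(axis=axes)
        m = params.momentum
        params.running_mean[t] = (1 - m) * params.running_mean[t] + m * mean
        params.running_var[t] = (1 - m) * params.running_var[t] + m * var
    elif mode == "eval":
        mean = params.running_mean[t]
        var = params.running_var[t]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    inv_std = 1.0 / np.sqrt(var + params.eps)
    xhat = (x - mean.reshape(bshape)) * inv_std.reshape(bshape)
    return params.scale[t].reshape(bshape) * xhat


@dataclass(frozen=True)
class LayerSpec:
    """One stage of the network.

    kind: 'conv' (3x3 same-padding LIF layer), 'pool' (2x2 average pooling
    of spikes), 'gap' (global average pool), 'linear' (output accumulator).
    """

    kind: str
    out_channels: int = 0
    kernel_size: int = 3
    neuron: NeuronParams = field(default_factory=NeuronParams)
    bntt: bool = False


@dataclass
class NetworkConfig:
    layers: tuple[LayerSpec, ...]
    total_timesteps: int
    num_classes: int
    input_shape: tuple[int, int, int]  # (C, H, W)

    def __post_init__(self) -> None:
        if self.total_timesteps < 1:
            raise ValueError("total_timesteps must be >= 1")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if not self.layers or self.layers[-1].kind != "linear":
            raise ValueError("last layer must be the linear output accumulator")

    @property
    def conv_indices(self) -> list[int]:
        return [i for i, l in enumerate(self.layers) if l.kind == "conv"]

    def layer_shapes(self) -> list[tuple[int, ...]]:
        """Output shape (C,H,W) or (C,) after each layer."""
        c, h, w = self.input_shape
        shapes: list[tuple[int, ...]] = []
        for spec in self.layers:
            if spec.kind == "conv":
                c = spec.out_channels
            elif spec.kind == "pool":
                if h % 2 or w % 2:
                    raise ValueError("pooling needs even spatial dims")
                h, w = h // 2, w // 2
            elif spec.kind == "gap":
                shapes.append((c,))
                continue
            elif spec.kind == "linear":
                c = spec.out_channels
                shapes.append((c,))
                continue
            else:
                raise ValueError(f"unknown layer kind {spec.kind!r}")
            shapes.append((c, h, w))
        return shapes


def config_to_dict(config: NetworkConfig) -> dict:
    return {
        "total_timesteps": config.total_timesteps,
        "num_classes": config.num_classes,
        "input_shape": list(config.input_shape),
        "layers": [
            {
                "kind": s.kind,
                "out_channels": s.out_channels,
                "kernel_size": s.kernel_size,
                "leak": s.neuron.leak,
                "threshold": "inf" if math.isinf(s.neuron.threshold) else s.neuron.threshold,
                "bntt": s.bntt,
            }
            for s in config.layers
        ],
    }


def config_from_dict(d: dict) -> NetworkConfig:
    layers = tuple(
        LayerSpec(
            ld["kind"],
            ld["out_channels"],
            ld["kernel_size"],
            NeuronParams(
                leak=ld["leak"],
                threshold=INF_THRESHOLD if ld["threshold"] == "inf" else float(ld["threshold"]),
            ),
            bntt=ld["bntt"],
        )
        for ld in d["layers"]
    )
    return NetworkConfig(
        layers, d["total_timesteps"], d["num_classes"], tuple(d["input_shape"])
    )


def standard_config(
    timesteps: int = 20,
    num_classes: int = 4,
    input_shape: tuple[int, int, int] = (1, 16, 16),
    channels: tuple[int, int, int] = (8, 16, 16),
    leak: float = 0.99,
    threshold: float = 1.0,
    bntt: bool = True,
) -> NetworkConfig:
    """Desk-scale default: 3 conv LIF layers, two pooling stages, GAP, linear."""
    np_ = NeuronParams(leak=leak, threshold=threshold)
    out_np = NeuronParams(leak=1.0, threshold=INF_THRESHOLD)
    layers = (
        LayerSpec("conv", channels[0], neuron=np_, bntt=bntt),
        LayerSpec("pool"),
        LayerSpec("conv", channels[1], neuron=np_, bntt=bntt),
        LayerSpec("pool"),
        LayerSpec("conv", channels[2], neuron=np_, bntt=bntt),
        LayerSpec("gap"),
        LayerSpec("linear", num_classes, neuron=out_np),
    )
    return NetworkConfig(layers, timesteps, num_classes, input_shape)


@dataclass
class LayerRecord:
    """Recorded binary spike raster [T, C, H, W] for one layer (single
    sample) plus, for the output layer, the accumulated potentials."""

    layer_index: int
    spikes: np.ndarray


class SpikingNetwork:
    """LIF network with explicit weights; supports recorded forward passes
    and surrogate-gradient backward passes (used by training, Grad-CAM and
    input-gradient attacks)."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator | None = None):
        self.config = config
        self.weights: dict[str, np.ndarray] = {}
        self.bntt: dict[int, BNTTParams] = {}
        self._init_params(rng or np.random.default_rng(0))

    def _init_params(self, rng: np.random.Generator) -> None:
        c_in = self.config.input_shape[0]
        feat = c_in
        for i, spec in enumerate(self.config.layers):
            if spec.kind == "conv":
                k = spec.kernel_size
                fan_in = feat * k * k
                self.weights[f"conv{i}.weight"] = rng.normal(
                    0.0, math.sqrt(2.0 / fan_in), size=(spec.out_channels, feat, k, k)
                )
                if spec.bntt:
                    self.bntt[i] = BNTTParams.init(
                        self.config.total_timesteps, spec.out_channels
                    )
                feat = spec.out_channels
            elif spec.kind == "linear":
                self.weights[f"linear{i}.weight"] = rng.normal(
                    0.0, math.sqrt(2.0 / feat), size=(spec.out_channels, feat)
                )

    # ------------------------------------------------------------------
    def forward(
        self,
        input_spikes: np.ndarray,
        record_layers: tuple[int, ...] | list[int] = (),
        mode: str = "eval",
        keep_cache: bool = False,
        drive_hook=None,
    ) -> dict:
        """Run the network over all T steps on a batched raster
        ``[T, B, Cin, H, W]``.

        Returns a dict with ``potentials`` [B, num_classes], ``records``
        mapping layer index -> [T, B, C, H, W] spikes, and (if
        ``keep_cache``) the per-step intermediates needed for backward.
        ``drive_hook(layer_index, t, drive)`` is called with each conv
        layer's raw (pre-normalization) drive — used by ANN-SNN threshold
        calibration.
        """
        cfg = self.config
        T = cfg.total_timesteps
        if input_spikes.ndim != 5:
            raise ValueError("input raster must be [T, B, C, H, W]")
        if input_spikes.shape[0] != T:
            raise ValueError(
                f"raster has {input_spikes.shape[0]} steps, config expects {T}"
            )
        vals = np.unique(input_spikes)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("input raster must be binary")
        b = input_spikes.shape[1]

        shapes = cfg.layer_shapes()
        states: dict[int, NeuronState] = {}
        for i, spec in enumerate(cfg.layers):
            if spec.kind in ("conv", "linear"):
                states[i] = NeuronState.zeros((b,) + shapes[i])

        records: dict[int, list[np.ndarray]] = {i: [] for i in record_layers}
        cache: dict = {"x": {}, "u": {}, "bn": {}} if keep_cache else None

        for t in range(T):
            x = input_spikes[t].astype(float)
            for i, spec in enumerate(cfg.layers):
                if spec.kind == "conv":
                    if keep_cache:
                        cache["x"].setdefault(i, []).append(x)
                    z = _layers.conv2d(x, self.weights[f"conv{i}.weight"])
                    if drive_hook is not None:
                        drive_hook(i, t, z)
                    if i in self.bntt:
                        z = self._bntt_forward(i, z, t, mode, cache)
                    states[i], x = lif_update(states[i], z, spec.neuron)
                    if keep_cache:
                        cache["u"].setdefault(i, []).append(states[i].potential)
                elif spec.kind == "pool":
                    x = _layers.avgpool2(x)
                elif spec.kind == "gap":
                    if keep_cache:
                        cache.setdefault("gap_in_shape", x.shape)
                    x = _layers.global_avgpool(x)
                elif spec.kind == "linear":
                    if keep_cache:
                        cache["x"].setdefault(i, []).append(x)
                    z = x @ self.weights[f"linear{i}.weight"].T
                    states[i], x = lif_update(states[i], z, spec.neuron)
                if i in records:
                    records[i].append(x.copy())

        out_index = len(cfg.layers) - 1
        result = {
            "potentials": states[out_index].potential,
            "records": {i: np.stack(r) for i, r in records.items()},
        }
        if keep_cache:
            result["cache"] = cache
        return result

    def _bntt_forward(self, i: int, z: np.ndarray, t: int, mode: str, cache) -> np.ndarray:
        params = self.bntt[i]
        if mode == "train":
            axes = (0, 2, 3)
            mean = z.mean(axis=axes)
            var = z.var(axis=axes)
            m = params.momentum
            params.running_mean[t] = (1 - m) * params.running_mean[t] + m * mean
            params.running_var[t] = (1 - m) * params.running_var[t] + m * var
        else:
            mean = params.running_mean[t]
            var = params.running_var[t]
        inv_std = 1.0 / np.sqrt(var + params.eps)
        xhat = (z - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out = params.scale[t][None, :, None, None] * xhat
        if cache is not None:
            cache["bn"].setdefault(i, []).append((xhat, inv_std))
        return out

    # ------------------------------------------------------------------
    def backward(
        self,
        cache: dict,
        seed_grad: np.ndarray,
        surrogate_width: float | None = None,
        need_input_grad: bool = False,
        capture_layer: int | None = None,
        bn_batch_stats: bool = False,
    ) -> dict:
        """Surrogate backpropagation through time.

        ``seed_grad`` is dL/d(output potentials) [B, num_classes].  Returns
        weight gradients, per-time-step BNTT scale gradients, optionally the
        summed input-raster gradient, and optionally the per-step gradient
        with respect to the spikes of ``capture_layer``.

        The spike nonlinearity is differentiated with a triangular
        pseudo-derivative of height 1 at u = threshold and half-width
        ``surrogate_width`` (default: the layer threshold).  Both the leak
        path and the soft-reset path carry gradient.
        """
        cfg = self.config
        T = cfg.total_timesteps
        out_index = len(cfg.layers) - 1
        wgrads = {k: np.zeros_like(v) for k, v in self.weights.items()}
        bngrads = {i: np.zeros_like(p.scale) for i, p in self.bntt.items()}
        du_next: dict[int, np.ndarray] = {}
        input_grad = None
        captured: list[np.ndarray] = []

        lin_w = self.weights[f"linear{out_index}.weight"]
        gap_shape = cache.get("gap_in_shape")

        for t in range(T - 1, -1, -1):
            # output accumulator: u_T = sum_t z_t  =>  dL/dz_t = seed
            g_t = cache["x"][out_index][t]  # GAP features at step t
            wgrads[f"linear{out_index}.weight"] += seed_grad.T @ g_t
            d = seed_grad @ lin_w  # dL/d gap features at t
            bb, cc, hh, ww = gap_shape
            d = _layers.global_avgpool_backward(d, hh, ww)
            # walk conv/pool stack in reverse
            for i in range(len(cfg.layers) - 1, -1, -1):
                spec = cfg.layers[i]
                if spec.kind in ("linear", "gap"):
                    continue
                if spec.kind == "pool":
                    d = _layers.avgpool2_backward(d)
                    continue
                # conv LIF layer: d is dL/do_t (downstream part)
                u_t = cache["u"][i][t]
                theta = spec.neuron.threshold
                leak = spec.neuron.leak
                width = surrogate_width if surrogate_width is not None else theta
                dun = du_next.get(i)
                g_o = d if dun is None else d - theta * dun
                if capture_layer == i:
                    captured.append(g_o)
                surr = np.maximum(0.0, 1.0 - np.abs(u_t - theta) / width)
                du = g_o * surr
                if dun is not None:
                    du = du + leak * dun
                du_next[i] = du
                dz = du
                if i in self.bntt:
                    xhat, inv_std = cache["bn"][i][t]
                    dz = self._bntt_backward(
                        i, t, dz, xhat, inv_std, bngrads, bn_batch_stats
                    )
                x_in = cache["x"][i][t]
                first_conv = i == cfg.conv_indices[0]
                dx, dw = _layers.conv2d_backward(
                    x_in,
                    self.weights[f"conv{i}.weight"],
                    dz,
                    need_dx=(not first_conv) or need_input_grad,
                )
                wgrads[f"conv{i}.weight"] += dw
                if first_conv:
                    if need_input_grad:
                        input_grad = dx if input_grad is None else input_grad + dx
                    break
                d = dx

        out = {"weights": wgrads, "bntt_scale": bngrads}
        if need_input_grad:
            out["input"] = input_grad
        if capture_layer is not None:
            captured.reverse()  # collected T-1 .. 0
            out["captured"] = np.stack(captured)
        return out

    def _bntt_backward(
        self,
        i: int,
        t: int,
        dy: np.ndarray,
        xhat: np.ndarray,
        inv_std: np.ndarray,
        bngrads: dict,
        batch_stats: bool,
    ) -> np.ndarray:
        params = self.bntt[i]
        scale = params.scale[t][None, :, None, None]
        bngrads[i][t] += (dy * xhat).sum(axis=(0, 2, 3))
        dxhat = dy * scale
        if not batch_stats:
            return dxhat * inv_std[None, :, None, None]
        # full batch-norm backward through mini-batch mean and variance
        axes = (0, 2, 3)
        n = dxhat.shape[0] * dxhat.shape[2] * dxhat.shape[3]
        m1 = dxhat.mean(axis=axes)[None, :, None, None]
        m2 = (dxhat * xhat).mean(axis=axes)[None, :, None, None]
        return (dxhat - m1 - xhat * m2) * inv_std[None, :, None, None]

    def copy(self) -> "SpikingNetwork":
        import copy as _copy

        return _copy.deepcopy(self)


def forward_network(
    config: NetworkConfig,
    weights: dict[str, np.ndarray],
    input_spikes: np.ndarray,
    record_layers: tuple[int, ...] | list[int] = (),
    bntt: dict[int, BNTTParams] | None = None,
) -> tuple[list[LayerRecord], np.ndarray]:
    """Functional single-sample forward pass.

    ``input_spikes``: binary [T, C, H, W].  Returns one :class:`LayerRecord`
    per requested layer (spikes [T, C, H, W]) and the output potentials per
    class after T steps.  Deterministic given weights and input.
    """
    net = SpikingNetwork(config)
    net.weights = dict(weights)
    if bntt:
        net.bntt = bntt
    elif net.bntt:
        # freshly initialized identity stats are fine for eval
        pass
    out = net.forward(input_spikes[:, None], record_layers=record_layers, mode="eval")
    recs = [
        LayerRecord(i, out["records"][i][:, 0]) for i in record_layers
    ]
    return recs, out["potentials"][0]
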