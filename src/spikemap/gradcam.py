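"""Gradient-based baseline explanations.

Standard Grad-CAM on the reference ReLU network serves as the ground-truth
map for localization error.  The spiking variant backpropagates a chosen
class logit through time with surrogate derivatives, accumulates one
channel weight per channel over all steps and positions, and produces one
ReLU-clamped weighted activation map per time-step.  Both require a class
label — unlike the spike activation map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ann import ReLUConvNet
from .metrics import heatmap_variance
from .sam import KernelParams, compute_sam, normalize_heatmaps
from .snn_core import SpikingNetwork

__all__ = [
    "SurrogateSpec",
    "surrogate_grad",
    "weighted_channel_sum",
    "snn_gradcam",
    "ann_gradcam",
    "heatmap_smoothing_probe",
]


@dataclass(frozen=True)
class SurrogateSpec:
    """Triangular pseudo-derivative: height 1 at u = threshold, reaching 0
    at |u - threshold| >= width."""

    width: float = 1.0

    def __post_init__(self) -> None:
        if not (self.width > 0):
            raise ValueError("width must be positive")


def surrogate_grad(u: np.ndarray, theta: float, spec: SurrogateSpec) -> np.ndarray:
    """max(0, 1 - |u - theta| / width)."""
    return np.maximum(0.0, 1.0 - np.abs(np.asarray(u, dtype=float) - theta) / spec.width)


def weighted_channel_sum(alpha: np.ndarray, activations: np.ndarray) -> np.ndarray:
    """ReLU-clamped channel-weighted sum: one map per leading index.

    alpha: [K]; activations: [K,H,W] or [T,K,H,W].
    """
    alpha = np.asarray(alpha, dtype=float)
    act = np.asarray(activations, dtype=float)
    if act.ndim == 3:
        return np.maximum(0.0, np.einsum("k,khw->hw", alpha, act))
    return np.maximum(0.0, np.einsum("k,tkhw->thw", alpha, act))


def snn_gradcam(
    net: SpikingNetwork,
    input_raster: np.ndarray,
    target_layer: int,
    class_label: int,
    normalize: bool = True,
) -> np.ndarray:
    """Heatmap sequence [T,H,W] for ``class_label`` at a recorded conv layer.

    Channel weights alpha are the class-logit gradients with respect to the
    layer's spike activations, accumulated over all steps and positions and
    divided by T*H*W; the map at each step is the ReLU of the alpha-weighted
    channel sum of that step's spikes.
    """
    if target_layer not in net.config.conv_indices:
        raise ValueError(f"layer {target_layer} is not a conv layer")
    if not (0 <= class_label < net.config.num_classes):
        raise ValueError("invalid class label")
    if input_raster.ndim == 4:
        input_raster = input_raster[:, None]
    out = net.forward(
        input_raster, record_layers=(target_layer,), keep_cache=True, mode="eval"
    )
    seed = np.zeros((input_raster.shape[1], net.config.num_classes))
    seed[:, class_label] = 1.0
    grads = net.backward(out["cache"], seed, capture_layer=target_layer)
    spikes = out["records"][target_layer][:, 0]  # [T,K,H,W]
    act_grad = grads["captured"][:, 0]  # [T,K,H,W]
    t_, k_, h, w = spikes.shape
    alpha = act_grad.sum(axis=(0, 2, 3)) / (t_ * h * w)  # one weight per channel
    maps = weighted_channel_sum(alpha, spikes)
    return normalize_heatmaps(maps) if normalize else maps


def ann_gradcam(
    ann: ReLUConvNet,
    image: np.ndarray,
    class_label: int,
    target_layer: int,
    normalize: bool = True,
) -> np.ndarray:
    """Standard Grad-CAM 2-D map at a conv layer of the reference network.

    image: [C,H,W] in [0,255].
    """
    if target_layer not in ann.config.conv_indices:
        raise ValueError(f"layer {target_layer} is not a conv layer")
    if not (0 <= class_label < ann.config.num_classes):
        raise ValueError("invalid class label")
    x = np.asarray(image, dtype=float)[None] / 255.0
    out = ann.forward(x, keep_cache=True)
    seed = np.zeros((1, ann.config.num_classes))
    seed[0, class_label] = 1.0
    grads = ann.backward(out["cache"], seed, capture_layer=target_layer)
    act = out["activations"][target_layer][0]  # [K,H,W]
    g = grads["captured"][0]  # [K,H,W]
    alpha = g.mean(axis=(1, 2))  # global-average-pooled gradients
    gcam = weighted_channel_sum(alpha, act)
    if normalize:
        m = gcam.max()
        if m > 0:
            gcam = gcam / m
    return gcam


def heatmap_smoothing_probe(
    net: SpikingNetwork,
    input_raster: np.ndarray,
    class_label: int,
    layers: list[int],
    kernel: KernelParams | None = None,
) -> list[dict]:
    """Max-over-time pixel variance of SAM vs. spiking Grad-CAM, per layer.

    Returns one row {method, layer, variance} per (method, layer).
    """
    if input_raster.ndim == 4:
        input_raster = input_raster[:, None]
    rec = net.forward(input_raster, record_layers=tuple(layers))
    rows = []
    for li in layers:
        raster = rec["records"][li][:, 0]
        samseq = normalize_heatmaps(compute_sam(raster, kernel))
        rows.append(
            {"method": "sam", "layer": li, "variance": heatmap_variance(samseq)}
        )
        gseq = snn_gradcam(net, input_raster, li, class_label)
        rows.append(
            {"method": "snn_gradcam", "layer": li, "variance": heatmap_variance(gseq)}
        )
    return rows
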