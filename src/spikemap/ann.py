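"""Reference ReLU network sharing the spiking network's topology.

Used as the Grad-CAM ground-truth, as the source model for ANN-SNN
conversion, and as the ANN target of the gradient-sign attack.  Weights use
the same names as the spiking network (``conv{i}.weight``,
``linear{i}.weight``) so conversion is a straight copy.
"""

from __future__ import annotations

import math

import numpy as np

from . import _layers
from .snn_core import NetworkConfig

__all__ = ["ReLUConvNet"]


class ReLUConvNet:
    """Bias-free conv/ReLU/avg-pool/GAP/linear network, inputs in [0,1]."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator | None = None):
        self.config = config
        self.weights: dict[str, np.ndarray] = {}
        rng = rng or np.random.default_rng(0)
        feat = config.input_shape[0]
        for i, spec in enumerate(config.layers):
            if spec.kind == "conv":
                k = spec.kernel_size
                self.weights[f"conv{i}.weight"] = rng.normal(
                    0.0,
                    math.sqrt(2.0 / (feat * k * k)),
                    size=(spec.out_channels, feat, k, k),
                )
                feat = spec.out_channels
            elif spec.kind == "linear":
                self.weights[f"linear{i}.weight"] = rng.normal(
                    0.0, math.sqrt(2.0 / feat), size=(spec.out_channels, feat)
                )

    def forward(self, x: np.ndarray, keep_cache: bool = False) -> dict:
        """x: [B,C,H,W] in [0,1].  Returns logits and optional cache."""
        cache: dict = {"x": {}, "z": {}} if keep_cache else None
        out_index = len(self.config.layers) - 1
        acts: dict[int, np.ndarray] = {}
        for i, spec in enumerate(self.config.layers):
            if spec.kind == "conv":
                if keep_cache:
                    cache["x"][i] = x
                z = _layers.conv2d(x, self.weights[f"conv{i}.weight"])
                if keep_cache:
                    cache["z"][i] = z
                x = np.maximum(z, 0.0)
                acts[i] = x
            elif spec.kind == "pool":
                x = _layers.avgpool2(x)
            elif spec.kind == "gap":
                if keep_cache:
                    cache["gap_in_shape"] = x.shape
                x = _layers.global_avgpool(x)
            elif spec.kind == "linear":
                if keep_cache:
                    cache["x"][i] = x
                x = x @ self.weights[f"linear{i}.weight"].T
        result = {"logits": x, "activations": acts}
        if keep_cache:
            result["cache"] = cache
        return result

    def backward(
        self,
        cache: dict,
        seed_grad: np.ndarray,
        need_input_grad: bool = False,
        capture_layer: int | None = None,
    ) -> dict:
        """Backpropagate dL/d(logits).  Optionally returns dL/d(input) and
        dL/d(ReLU activations) at ``capture_layer``."""
        cfg = self.config
        out_index = len(cfg.layers) - 1
        wgrads = {k: np.zeros_like(v) for k, v in self.weights.items()}
        lin_w = self.weights[f"linear{out_index}.weight"]
        wgrads[f"linear{out_index}.weight"] += seed_grad.T @ cache["x"][out_index]
        d = seed_grad @ lin_w
        bb, cc, hh, ww = cache["gap_in_shape"]
        d = _layers.global_avgpool_backward(d, hh, ww)
        captured = None
        input_grad = None
        conv_first = cfg.conv_indices[0] if cfg.conv_indices else None
        for i in range(len(cfg.layers) - 1, -1, -1):
            spec = cfg.layers[i]
            if spec.kind in ("linear", "gap"):
                continue
            if spec.kind == "pool":
                d = _layers.avgpool2_backward(d)
                continue
            if capture_layer == i:
                captured = d.copy()  # grad w.r.t. ReLU output
            dz = d * (cache["z"][i] > 0)
            dx, dw = _layers.conv2d_backward(
                cache["x"][i],
                self.weights[f"conv{i}.weight"],
                dz,
                need_dx=(i != conv_first) or need_input_grad,
            )
            wgrads[f"conv{i}.weight"] += dw
            if i == conv_first:
                input_grad = dx
                break
            d = dx
        if need_input_grad and input_grad is None:
            input_grad = d  # no conv layers: gradient below the pool stack
        out = {"weights": wgrads}
        if need_input_grad:
            out["input"] = input_grad
        if capture_layer is not None:
            out["captured"] = captured
        return out

    def predict(self, images: np.ndarray) -> np.ndarray:
        """images: [B,C,H,W] in [0,255] -> argmax class indices."""
        logits = self.forward(np.asarray(images, dtype=float) / 255.0)["logits"]
        return logits.argmax(axis=1)

    def copy(self) -> "ReLUConvNet":
        import copy as _copy

        return _copy.deepcopy(self)
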