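"""Single-step gradient-sign adversarial attacks.

For the ReLU network the input gradient is exact; for the spiking network
the loss gradient is accumulated over all time-steps by surrogate
backpropagation and taken with respect to the analog image that
parameterizes the Poisson firing rates (raw per-step gradients are summed
first, the sign is taken once).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ann import ReLUConvNet
from .encoding import poisson_encode, validate_image
from .snn_core import SpikingNetwork
from .training import _log_softmax

__all__ = ["AttackConfig", "fgsm"]


@dataclass(frozen=True)
class AttackConfig:
    epsilon: float = 4.0 / 255.0  # budget in normalized [0,1] pixel units
    mode: str = "ann"  # 'ann' | 'snn'

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.mode not in ("ann", "snn"):
            raise ValueError("mode must be 'ann' or 'snn'")


def fgsm(
    model: ReLUConvNet | SpikingNetwork,
    image: np.ndarray,
    label: int,
    cfg: AttackConfig,
    encode_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """x_adv = clip(x + eps * sign(dL/dx), 0, 1), rescaled to [0,255].

    Returns (adversarial image [C,H,W] in [0,255], exact float perturbation
    in normalized units).  ``encode_seed`` fixes the Poisson sampling for
    the spiking mode.
    """
    img = validate_image(image)
    x = img / 255.0
    if cfg.mode == "ann":
        g = _ann_input_grad(model, x, label)
    else:
        g = _snn_input_grad(model, img, label, encode_seed)
    pert = cfg.epsilon * np.sign(g)
    x_adv = np.clip(x + pert, 0.0, 1.0)
    return x_adv * 255.0, x_adv - x


def _ann_input_grad(ann: ReLUConvNet, x: np.ndarray, label: int) -> np.ndarray:
    out = ann.forward(x[None], keep_cache=True)
    lsm = _log_softmax(out["logits"])
    seed = np.exp(lsm)
    seed[0, label] -= 1.0  # d(cross-entropy)/d(logits)
    grads = ann.backward(out["cache"], seed, need_input_grad=True)
    return grads["input"][0]


def _snn_input_grad(
    net: SpikingNetwork, image: np.ndarray, label: int, encode_seed: int
) -> np.ndarray:
    raster = poisson_encode(image, net.config.total_timesteps, encode_seed)
    out = net.forward(raster[:, None], keep_cache=True)
    lsm = _log_softmax(out["potentials"])
    seed = np.exp(lsm)
    seed[0, label] -= 1.0
    grads = net.backward(out["cache"], seed, need_input_grad=True)
    # summed over time inside backward; rate = x so d(rate)/dx = 1
    return grads["input"][0]
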