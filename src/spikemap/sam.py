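"""Spike activation maps (SAM).

Each past spike of a neuron contributes exp(-gamma * gap) toward the
present (the temporal-spike contribution score, TSCS); summing over all
strictly-previous spike times gives the neuronal contribution score (NCS),
maintained incrementally as

    N_t = exp(-gamma) * (N_{t-1} + s_{t-1}),   N_0 = 0,

which equals the explicit sum over the spike-time set.  The heatmap at step
t is the channel sum of N_t * s_t.  No labels, no gradients: only the
forward spike raster is consumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "KernelParams",
    "tscs_kernel",
    "ncs_step",
    "ncs_sequence",
    "compute_sam",
    "normalize_heatmaps",
    "resize_heatmap",
]

#: Default kernel steepness; mid-range between the flat (0) and
#: near-sighted (1) regimes, both of which degrade localization.
DEFAULT_GAMMA = 0.2


@dataclass(frozen=True)
class KernelParams:
    gamma: float = DEFAULT_GAMMA

    def __post_init__(self) -> None:
        if not (self.gamma >= 0.0 and math.isfinite(self.gamma)):
            raise ValueError(f"gamma must be finite and >= 0, got {self.gamma}")


def tscs_kernel(t: int, t_prev: int, params: KernelParams) -> float:
    """Contribution of a spike at ``t_prev`` toward time ``t``:
    exp(-gamma * |t - t_prev|)."""
    if t_prev > t:
        raise ValueError("t_prev must not exceed t")
    return math.exp(-params.gamma * abs(t - t_prev))


def ncs_step(
    prev_scores: np.ndarray, prev_spikes: np.ndarray, params: KernelParams
) -> np.ndarray:
    """Advance NCS by one step: N_t = exp(-gamma) * (N_{t-1} + s_{t-1})."""
    prev_scores = np.asarray(prev_scores, dtype=float)
    prev_spikes = np.asarray(prev_spikes)
    if prev_scores.shape != prev_spikes.shape:
        raise ValueError("score/spike shape mismatch")
    if not np.all(np.isin(np.unique(prev_spikes), (0, 1))):
        raise ValueError("prev_spikes must be binary")
    return math.exp(-params.gamma) * (prev_scores + prev_spikes)


def ncs_sequence(raster: np.ndarray, params: KernelParams) -> np.ndarray:
    """NCS at every step for a raster whose leading axis is time."""
    T = raster.shape[0]
    out = np.zeros_like(raster, dtype=float)
    for t in range(1, T):
        out[t] = ncs_step(out[t - 1], raster[t - 1], params)
    return out


def compute_sam(raster: np.ndarray, params: KernelParams | None = None) -> np.ndarray:
    """Heatmap sequence [T,H,W] from a binary spike raster [T,K,H,W].

    M_t = sum_k N_t * s_t: a single forward sweep, label-free and
    gradient-free.  Values are non-negative; normalize separately.
    """
    params = params or KernelParams()
    raster = np.asarray(raster)
    if raster.size == 0:
        raise ValueError("empty raster")
    if raster.ndim != 4:
        raise ValueError(f"raster must be [T,K,H,W], got shape {raster.shape}")
    if not np.all(np.isin(np.unique(raster), (0, 1))):
        raise ValueError("raster must be binary")
    ncs = ncs_sequence(raster.astype(float), params)
    return (ncs * raster).sum(axis=1)


def normalize_heatmaps(seq: np.ndarray, per_step: bool = False) -> np.ndarray:
    """Scale a non-negative heatmap sequence into [0,1].

    Default: divide by the single global maximum across all time-steps of
    the sample, preserving the relative temporal evolution.  ``per_step``
    normalizes each map independently instead.  All-zero input stays zero.
    """
    seq = np.asarray(seq, dtype=float)
    if not np.all(np.isfinite(seq)):
        raise ValueError("non-finite heatmap values")
    if seq.min() < 0:
        raise ValueError("heatmaps must be non-negative")
    if per_step:
        denom = seq.max(axis=tuple(range(1, seq.ndim)), keepdims=True)
        return np.where(denom > 0, seq / np.where(denom > 0, denom, 1.0), 0.0)
    m = seq.max()
    return seq / m if m > 0 else seq.copy()


def resize_heatmap(heatmap: np.ndarray, target_rows: int, target_cols: int) -> np.ndarray:
    """Bilinear, corner-aligned resize of a single 2-D map."""
    hm = np.asarray(heatmap, dtype=float)
    if hm.ndim != 2:
        raise ValueError("heatmap must be 2-D")
    if target_rows < 1 or target_cols < 1:
        raise ValueError("target sizes must be >= 1")
    h, w = hm.shape
    if (h, w) == (target_rows, target_cols):
        return hm.copy()
    rows = (
        np.linspace(0.0, h - 1.0, target_rows)
        if target_rows > 1
        else np.array([(h - 1) / 2.0])
    )
    cols = (
        np.linspace(0.0, w - 1.0, target_cols)
        if target_cols > 1
        else np.array([(w - 1) / 2.0])
    )
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(hm, [rr, cc], order=1, mode="nearest")
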