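"""Quantitative evaluation of heatmap sequences.

- localization error: min-over-time binary cross-entropy between a
  normalized heatmap sequence and a reference map (standard non-negative
  sign convention; values clamped away from {0,1} before the logs);
- pixel-wise variance (max over time): discriminativeness probe;
- normalized L1 distance (max over time): robustness probe;
- mask localization score: fraction of heatmap mass inside a ground-truth
  mask, best over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sam import resize_heatmap

__all__ = [
    "LocalizationResult",
    "localization_error",
    "heatmap_variance",
    "heatmap_l1",
    "mask_localization_score",
]

CLAMP_DELTA = 1e-6


@dataclass(frozen=True)
class LocalizationResult:
    error: float
    argmin_step: int
    trace: np.ndarray  # per-time-step error


def _check_unit_range(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} has non-finite values")
    if a.min() < 0 or a.max() > 1:
        raise ValueError(f"{name} must be normalized to [0,1]")
    return a


def localization_error(
    sam_seq: np.ndarray, reference: np.ndarray, delta: float = CLAMP_DELTA
) -> LocalizationResult:
    """Min-over-time cross-entropy between heatmaps [T,H,W] and a reference
    2-D map.  The reference is resized to the sequence's resolution."""
    seq = _check_unit_range(sam_seq, "heatmap sequence")
    ref = _check_unit_range(reference, "reference")
    if seq.ndim != 3:
        raise ValueError("sequence must be [T,H,W]")
    t_, h, w = seq.shape
    if ref.shape != (h, w):
        ref = resize_heatmap(ref, h, w)
    m = np.clip(seq, delta, 1.0 - delta)
    g = ref[None]
    per_pixel = -(g * np.log(m) + (1.0 - g) * np.log(1.0 - m))
    trace = per_pixel.mean(axis=(1, 2))
    k = int(np.argmin(trace))
    return LocalizationResult(float(trace[k]), k, trace)


def heatmap_variance(seq: np.ndarray) -> float:
    """Maximum over time of the population variance of pixel values."""
    seq = np.asarray(seq, dtype=float)
    if seq.size == 0:
        raise ValueError("empty sequence")
    if seq.ndim == 2:
        seq = seq[None]
    return float(seq.var(axis=tuple(range(1, seq.ndim))).max())


def heatmap_l1(seq_a: np.ndarray, seq_b: np.ndarray) -> float:
    """Maximum over time of the mean absolute pixel difference between two
    normalized heatmap sequences of identical shape.  Result in [0,1]."""
    a = _check_unit_range(seq_a, "seq_a")
    b = _check_unit_range(seq_b, "seq_b")
    if a.ndim == 2:
        a = a[None]
    if b.ndim == 2:
        b = b[None]
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    per_t = np.abs(a - b).mean(axis=tuple(range(1, a.ndim)))
    return float(per_t.max())


def mask_localization_score(seq: np.ndarray, mask: np.ndarray) -> float:
    """Best-over-time fraction of heatmap mass falling inside a binary
    ground-truth mask.  Zero when every map is zero."""
    seq = np.asarray(seq, dtype=float)
    if seq.ndim == 2:
        seq = seq[None]
    mask = np.asarray(mask)
    if not np.all(np.isin(np.unique(mask), (0, 1))):
        raise ValueError("mask must be binary")
    h, w = mask.shape
    if seq.shape[1:] != (h, w):
        seq = np.stack([resize_heatmap(m, h, w) for m in seq])
    total = seq.sum(axis=(1, 2))
    inside = (seq * mask[None]).sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, inside / np.where(total > 0, total, 1.0), 0.0)
    return float(frac.max())
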