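"""Poisson rate coding: static images to binary spike rasters.

Each pixel fires independently at every time-step with probability
``intensity / 255``, so the expected spike count over T steps is
proportional to pixel intensity.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

__all__ = ["validate_image", "poisson_encode", "load_png", "save_png"]


def validate_image(image: np.ndarray) -> np.ndarray:
    """Check an image tensor [C,H,W] with integer intensities in [0,255]."""
    img = np.asarray(image)
    if img.ndim == 2:
        img = img[None]
    if img.ndim != 3 or img.size == 0:
        raise ValueError(f"image must be [C,H,W], got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image has non-finite values")
    if img.min() < 0 or img.max() > 255:
        raise ValueError(
            f"pixel values outside [0,255]: min {img.min()}, max {img.max()}"
        )
    return img.astype(float)


def poisson_encode(
    image: np.ndarray, timesteps: int, rng_seed: int | np.random.Generator
) -> np.ndarray:
    """Encode an image [C,H,W] as a binary raster [T,C,H,W].

    Spike iff uniform(0,1) < p/255 per pixel per step, independently.
    Deterministic given ``rng_seed`` (an int seed or a Generator).
    """
    img = validate_image(image)
    if timesteps < 1:
        raise ValueError("timesteps must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    rates = img / 255.0
    u = rng.random(size=(timesteps,) + img.shape)
    return (u < rates).astype(float)


def poisson_encode_batch(
    images: np.ndarray, timesteps: int, rng_seed: int | np.random.Generator
) -> np.ndarray:
    """Encode a stack of images [B,C,H,W] as a raster [T,B,C,H,W]."""
    imgs = np.asarray(images, dtype=float)
    if imgs.ndim != 4:
        raise ValueError("expected [B,C,H,W]")
    if imgs.min() < 0 or imgs.max() > 255:
        raise ValueError("pixel values outside [0,255]")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    u = rng.random(size=(timesteps,) + imgs.shape)
    return (u < imgs / 255.0).astype(float)


def load_png(path) -> np.ndarray:
    """Read a PNG into an ImageTensor [C,H,W], uint8 values."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 2:
        arr = arr[None]
    else:
        arr = arr.transpose(2, 0, 1)
    return validate_image(arr)


def save_png(path, image: np.ndarray) -> None:
    img = validate_image(image)
    arr = np.clip(np.round(img), 0, 255).astype(np.uint8)
    if arr.shape[0] == 1:
        Image.fromarray(arr[0], mode="L").save(path)
    else:
        Image.fromarray(arr.transpose(1, 2, 0)).save(path)
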