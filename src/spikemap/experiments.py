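"""Desk-scale evaluation protocol.

Builds the synthetic testbed (4-class 16x16 glyphs), trains the three
models (surrogate-gradient SNN at T=20, reference ReLU net, converted SNN
at T=128), and measures the quantities behind the headline comparisons:
mask-localization of label-free heatmaps, localization error versus the
reference Grad-CAM across kernel steepness and depth, heatmap variance,
temporal spike-count profiles, adversarial robustness, and conversion
fidelity.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ann import ReLUConvNet
from .attacks import AttackConfig, fgsm
from .encoding import poisson_encode
from .gradcam import ann_gradcam, snn_gradcam
from .metrics import (
    heatmap_l1,
    heatmap_variance,
    localization_error,
    mask_localization_score,
)
from .sam import KernelParams, compute_sam, normalize_heatmaps
from .snn_core import SpikingNetwork, standard_config
from .synthetic_data import ShapeDataset, make_shape_dataset
from .training import (
    TrainConfig,
    convert_ann_to_snn,
    snn_predict,
    train_ann,
    train_snn,
)

PROBE_LAYERS = (0, 2, 4)  # conv layers: shallow (16x16), mid (8x8), deep (4x4)
DEFAULT_GAMMA = 0.2


@dataclass
class Testbed:
    dataset: ShapeDataset
    surrogate: SpikingNetwork
    ann: ReLUConvNet
    converted: SpikingNetwork
    surrogate_history: list
    ann_history: list
    conversion_report: object
    seed: int


def build_testbed(
    seed: int = 1,
    n_per_class: int = 100,
    surrogate_epochs: int = 10,
    ann_epochs: int = 40,
    surrogate_timesteps: int = 20,
    converted_timesteps: int = 128,
    calibration_size: int = 64,
) -> Testbed:
    """Generate data and train all three models."""
    ds = make_shape_dataset(
        n_classes=4, image_size=16, n_per_class=n_per_class, noise_level=0.15,
        rng_seed=seed,
    )
    snn_cfg = standard_config(timesteps=surrogate_timesteps)
    surrogate, s_hist = train_snn(ds, snn_cfg, TrainConfig(epochs=surrogate_epochs, seed=seed))
    ann_cfg = standard_config(bntt=False)
    ann, a_hist = train_ann(ds, ann_cfg, TrainConfig(epochs=ann_epochs, seed=seed))
    converted, report = convert_ann_to_snn(
        ann,
        ds.subset("train").images[:calibration_size],
        timesteps=converted_timesteps,
        seed=seed,
    )
    return Testbed(ds, surrogate, ann, converted, s_hist, a_hist, report, seed)


def sam_sequences(
    net: SpikingNetwork,
    image: np.ndarray,
    layers: tuple[int, ...],
    gammas: tuple[float, ...],
    rng,
) -> dict:
    """One forward pass; normalized SAM per (layer, gamma)."""
    raster = poisson_encode(image, net.config.total_timesteps, rng)
    rec = net.forward(raster[:, None], record_layers=layers)
    out = {}
    for li in layers:
        spikes = rec["records"][li][:, 0]
        for g in gammas:
            out[(li, g)] = normalize_heatmaps(compute_sam(spikes, KernelParams(g)))
    return out


def localization_table(
    testbed: Testbed,
    n_images: int = 50,
    layers: tuple[int, ...] = PROBE_LAYERS,
    gammas: tuple[float, ...] = (0.0, DEFAULT_GAMMA, 1.0),
    eval_seed: int = 1234,
) -> dict:
    """Mean localization error vs. the reference Grad-CAM, per
    (training method, kernel gamma, layer)."""
    test = testbed.dataset.subset("test")
    n = min(n_images, len(test))
    rng = np.random.default_rng(eval_seed)
    refs = {}
    errs = {
        (m, g, li): []
        for m in ("surrogate", "converted")
        for g in gammas
        for li in layers
    }
    for i in range(n):
        img, lab = test.images[i], int(test.labels[i])
        for li in layers:
            refs[li] = ann_gradcam(testbed.ann, img, lab, li)
        for method, net in (("surrogate", testbed.surrogate), ("converted", testbed.converted)):
            seqs = sam_sequences(net, img, layers, gammas, rng)
            for (li, g), seq in seqs.items():
                errs[(method, g, li)].append(localization_error(seq, refs[li]).error)
    return {k: float(np.mean(v)) for k, v in errs.items()}


def mask_concentration(
    testbed: Testbed,
    net: SpikingNetwork | None = None,
    n_images: int = 60,
    layer: int = 0,
    gamma: float = DEFAULT_GAMMA,
    eval_seed: int = 77,
) -> dict:
    """Label-free heatmaps vs. ground-truth masks: fraction of images whose
    best-over-time in-mask mass exceeds twice the mask's area fraction."""
    net = net or testbed.surrogate
    test = testbed.dataset.subset("test")
    n = min(n_images, len(test))
    rng = np.random.default_rng(eval_seed)
    hits, scores, areas = [], [], []
    for i in range(n):
        seq = sam_sequences(net, test.images[i], (layer,), (gamma,), rng)[(layer, gamma)]
        score = mask_localization_score(seq, test.masks[i])
        area = float(test.masks[i].mean())
        hits.append(score > 2.0 * area)
        scores.append(score)
        areas.append(area)
    return {
        "hit_rate": float(np.mean(hits)),
        "mean_score": float(np.mean(scores)),
        "mean_area": float(np.mean(areas)),
    }


def variance_comparison(
    testbed: Testbed,
    n_images: int = 30,
    layer: int = 0,
    gamma: float = DEFAULT_GAMMA,
    eval_seed: int = 55,
) -> dict:
    """Max-over-time pixel variance: label-free heatmaps vs. the surrogate
    spiking Grad-CAM, at the shallowest probed layer."""
    test = testbed.dataset.subset("test")
    net = testbed.surrogate
    n = min(n_images, len(test))
    rng = np.random.default_rng(eval_seed)
    v_sam, v_gc = [], []
    for i in range(n):
        img, lab = test.images[i], int(test.labels[i])
        raster = poisson_encode(img, net.config.total_timesteps, rng)
        rec = net.forward(raster[:, None], record_layers=(layer,))
        seq = normalize_heatmaps(compute_sam(rec["records"][layer][:, 0], KernelParams(gamma)))
        v_sam.append(heatmap_variance(seq))
        v_gc.append(heatmap_variance(snn_gradcam(net, raster, layer, lab)))
    return {"sam": float(np.mean(v_sam)), "snn_gradcam": float(np.mean(v_gc))}


def spike_count_cv(
    testbed: Testbed, n_images: int = 20, eval_seed: int = 11
) -> dict:
    """Coefficient of variation of the image-averaged per-step total spike
    count (all conv layers summed), per training method."""
    test = testbed.dataset.subset("test")
    out = {}
    for name, net in (("surrogate", testbed.surrogate), ("converted", testbed.converted)):
        rng = np.random.default_rng(eval_seed)
        profiles = []
        for i in range(min(n_images, len(test))):
            raster = poisson_encode(test.images[i], net.config.total_timesteps, rng)
            rec = net.forward(raster[:, None], record_layers=tuple(net.config.conv_indices))
            counts = sum(
                rec["records"][li].sum(axis=(1, 2, 3, 4))
                for li in net.config.conv_indices
            )
            profiles.append(counts)
        mean_profile = np.mean(profiles, axis=0)
        out[name] = float(mean_profile.std() / mean_profile.mean())
    return out


def fgsm_robustness(
    testbed: Testbed,
    n_images: int = 50,
    epsilon: float = 4.0 / 255.0,
    eps_grid: tuple[float, ...] = (0, 1 / 255, 2 / 255, 4 / 255, 8 / 255),
    layer: int = 0,
    gamma: float = DEFAULT_GAMMA,
    eval_seed: int = 31,
) -> dict:
    """Accuracy-vs-epsilon curve for the reference net, and the mean
    max-over-time normalized L1 distance between clean and adversarial
    heatmaps for both explanation routes at the given epsilon.

    Clean and adversarial spike rasters share the Poisson sample (common
    random numbers) so the distance reflects the perturbation, not
    resampling noise.
    """
    test = testbed.dataset.subset("test")
    ann, snn = testbed.ann, testbed.surrogate
    n = min(n_images, len(test))
    acc_curve = []
    for eps in eps_grid:
        correct = 0
        for i in range(n):
            img, lab = test.images[i], int(test.labels[i])
            adv, _ = fgsm(ann, img, lab, AttackConfig(eps, "ann"))
            correct += int(ann.predict(adv[None])[0] == lab)
        acc_curve.append(correct / n)
    l1_ann, l1_snn = [], []
    T = snn.config.total_timesteps
    for i in range(n):
        img, lab = test.images[i], int(test.labels[i])
        adv_a, _ = fgsm(ann, img, lab, AttackConfig(epsilon, "ann"))
        l1_ann.append(
            heatmap_l1(
                ann_gradcam(ann, img, lab, layer),
                ann_gradcam(ann, adv_a, lab, layer),
            )
        )
        adv_s, _ = fgsm(
            snn, img, lab, AttackConfig(epsilon, "snn"), encode_seed=eval_seed + i
        )
        kp = KernelParams(gamma)
        common = eval_seed + 10_000 + i
        seqs = []
        for x in (img, adv_s):
            raster = poisson_encode(x, T, common)
            rec = snn.forward(raster[:, None], record_layers=(layer,))
            seqs.append(normalize_heatmaps(compute_sam(rec["records"][layer][:, 0], kp)))
        l1_snn.append(heatmap_l1(*seqs))
    return {
        "eps_grid": list(eps_grid),
        "ann_accuracy": acc_curve,
        "l1_ann_gradcam": float(np.mean(l1_ann)),
        "l1_snn_sam": float(np.mean(l1_snn)),
    }


def conversion_fidelity(testbed: Testbed, eval_seed: int = 21) -> dict:
    """Prediction agreement between the converted spiking network and its
    source ReLU network on the full test split."""
    test = testbed.dataset.subset("test")
    ann_pred = testbed.ann.predict(test.images)
    snn_pred = snn_predict(testbed.converted, test.images, seed=eval_seed)
    return {
        "agreement": float((ann_pred == snn_pred).mean()),
        "ann_accuracy": float((ann_pred == test.labels).mean()),
        "snn_accuracy": float((snn_pred == test.labels).mean()),
        "thresholds": {int(k): float(v) for k, v in testbed.conversion_report.thresholds.items()},
    }
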