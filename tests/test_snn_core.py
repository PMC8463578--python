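import numpy as np
import pytest

from spikemap.encoding import poisson_encode_batch
from spikemap.snn_core import (
    BNTTParams,
    INF_THRESHOLD,
    NeuronParams,
    NeuronState,
    SpikingNetwork,
    bntt_normalize,
    config_from_dict,
    config_to_dict,
    forward_network,
    lif_update,
    standard_config,
)


def run_lif(drives, leak, threshold):
    state = NeuronState.zeros((1,))
    params = NeuronParams(leak, threshold)
    us, spikes = [], []
    for d in drives:
        state, s = lif_update(state, np.array([d]), params)
        us.append(state.potential[0])
        spikes.append(s[0])
    return np.array(us), np.array(spikes)


class TestLIFUpdate:
    def test_pure_accumulator(self):
        us, spikes = run_lif([0.5, 0.5, 0.5], leak=1.0, threshold=INF_THRESHOLD)
        assert np.allclose(us, [0.5, 1.0, 1.5])
        assert not spikes.any()

    def test_hand_trace_soft_reset(self):
        # u1=0.6 (no spike), u2=1.2 (spike), u3=1.2+0.6-1.0=0.8 (no spike)
        us, spikes = run_lif([0.6, 0.6, 0.6], leak=1.0, threshold=1.0)
        assert np.allclose(us, [0.6, 1.2, 0.8])
        assert spikes.tolist() == [0.0, 1.0, 0.0]

    def test_leak_geometric_limit(self):
        us, _ = run_lif([1.0] * 60, leak=0.5, threshold=INF_THRESHOLD)
        assert us[-1] == pytest.approx(1.0 / (1.0 - 0.5), abs=1e-9)

    def test_shape_mismatch_rejected(self):
        state = NeuronState.zeros((3,))
        with pytest.raises(ValueError, match="shape"):
            lif_update(state, np.zeros(4), NeuronParams())

    def test_nonfinite_input_rejected(self):
        state = NeuronState.zeros((2,))
        with pytest.raises(ValueError, match="finite"):
            lif_update(state, np.array([np.nan, 0.0]), NeuronParams())

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            NeuronParams(leak=1.5)
        with pytest.raises(ValueError):
            NeuronParams(threshold=0.0)

    def test_spikes_binary_and_reset_uses_previous_spike(self):
        rng = np.random.default_rng(0)
        state = NeuronState.zeros((50,))
        params = NeuronParams(0.9, 1.0)
        prev_spikes = np.zeros(50)
        for _ in range(40):
            drive = rng.uniform(0, 1.5, size=50)
            expected_u = 0.9 * state.potential + drive - 1.0 * prev_spikes
            state, s = lif_update(state, drive, params)
            assert np.allclose(state.potential, expected_u)
            assert set(np.unique(s)) <= {0.0, 1.0}
            prev_spikes = s

    def test_spike_count_monotone_in_drive(self):
        totals = []
        for d in np.linspace(0.1, 1.5, 12):
            _, spikes = run_lif([d] * 30, leak=1.0, threshold=1.0)
            totals.append(spikes.sum())
        assert all(b >= a for a, b in zip(totals, totals[1:]))


class TestBNTT:
    def test_identity_parameters(self):
        p = BNTTParams.init(4, 3, eps=1e-12)
        x = np.random.default_rng(1).normal(size=(5, 3, 2, 2))
        out = bntt_normalize(x, p, t=0, mode="eval")
        assert np.allclose(out, x, atol=1e-5)

    def test_constant_batch_zero_variance(self):
        p = BNTTParams.init(4, 1)
        x = np.full((6, 1), 3.7)
        out = bntt_normalize(x, p, t=2, mode="train")
        assert np.all(np.isfinite(out))
        assert np.allclose(out, 0.0)

    def test_two_point_batch(self):
        p = BNTTParams.init(2, 1, eps=1e-14)
        x = np.array([[0.0], [2.0]])
        out = bntt_normalize(x, p, t=0, mode="train")
        assert np.allclose(out.ravel(), [-1.0, 1.0], atol=1e-6)

    def test_time_index_out_of_range(self):
        p = BNTTParams.init(4, 1)
        with pytest.raises(IndexError):
            bntt_normalize(np.zeros((2, 1)), p, t=4)

    def test_eval_is_deterministic_affine(self):
        rng = np.random.default_rng(2)
        p = BNTTParams(
            scale=rng.uniform(0.5, 2, (3, 2)),
            running_mean=rng.normal(size=(3, 2)),
            running_var=rng.uniform(0.5, 2, (3, 2)),
        )
        x = rng.normal(size=(4, 2))
        y = rng.normal(size=(4, 2))
        a = bntt_normalize(x, p, 1, "eval")
        b = bntt_normalize(y, p, 1, "eval")
        # affine => f(x) - f(y) is linear in x - y with per-channel slope
        slope = p.scale[1] / np.sqrt(p.running_var[1] + p.eps)
        assert np.allclose(a - b, (x - y) * slope)
        assert np.allclose(a, bntt_normalize(x, p, 1, "eval"))

    def test_train_updates_running_stats(self):
        p = BNTTParams.init(2, 1)
        x = np.random.default_rng(3).normal(5.0, 2.0, size=(64, 1))
        before = p.running_mean[0].copy()
        bntt_normalize(x, p, 0, "train")
        assert p.running_mean[0] != before


class TestForwardNetwork:
    def test_zero_input_silent_network(self):
        cfg = standard_config(timesteps=5, bntt=False)
        net = SpikingNetwork(cfg, np.random.default_rng(0))
        raster = np.zeros((5, 1, 16, 16))
        recs, pot = forward_network(cfg, net.weights, raster, record_layers=cfg.conv_indices)
        assert np.allclose(pot, 0.0)
        for r in recs:
            assert not r.spikes.any()

    def test_output_accumulates_linear_drive(self):
        from spikemap.snn_core import LayerSpec, NetworkConfig

        cfg = NetworkConfig(
            layers=(
                LayerSpec("gap"),
                LayerSpec("linear", 3, neuron=NeuronParams(1.0, INF_THRESHOLD)),
            ),
            total_timesteps=4,
            num_classes=3,
            input_shape=(2, 4, 4),
        )
        net = SpikingNetwork(cfg, np.random.default_rng(1))
        w = net.weights["linear1.weight"]
        raster = (np.random.default_rng(2).random((4, 1, 2, 4, 4)) < 0.5).astype(float)
        out = net.forward(raster)
        expected = sum(raster[t, 0].mean(axis=(1, 2)) @ w.T for t in range(4))
        assert np.allclose(out["potentials"][0], expected)

    def test_determinism(self):
        cfg = standard_config(timesteps=6)
        net = SpikingNetwork(cfg, np.random.default_rng(4))
        raster = poisson_encode_batch(
            np.random.default_rng(5).integers(0, 256, (2, 1, 16, 16)), 6, 9
        )
        a = net.forward(raster, record_layers=cfg.conv_indices)
        b = net.forward(raster, record_layers=cfg.conv_indices)
        assert np.array_equal(a["potentials"], b["potentials"])
        for li in cfg.conv_indices:
            assert np.array_equal(a["records"][li], b["records"][li])

    def test_records_binary_full_length(self):
        cfg = standard_config(timesteps=7)
        net = SpikingNetwork(cfg, np.random.default_rng(6))
        raster = poisson_encode_batch(
            np.random.default_rng(7).integers(0, 256, (3, 1, 16, 16)), 7, 8
        )
        out = net.forward(raster, record_layers=cfg.conv_indices)
        for li in cfg.conv_indices:
            rec = out["records"][li]
            assert rec.shape[0] == 7
            assert set(np.unique(rec)) <= {0.0, 1.0}

    def test_wrong_timestep_count_rejected(self):
        cfg = standard_config(timesteps=5)
        net = SpikingNetwork(cfg)
        with pytest.raises(ValueError, match="steps"):
            net.forward(np.zeros((4, 1, 1, 16, 16)))

    def test_nonbinary_input_rejected(self):
        cfg = standard_config(timesteps=2)
        net = SpikingNetwork(cfg)
        with pytest.raises(ValueError, match="binary"):
            net.forward(np.full((2, 1, 1, 16, 16), 0.5))

    def test_potential_conservation_accumulator(self):
        # leak 1, infinite threshold: potential == summed drive
        from spikemap.snn_core import LayerSpec, NetworkConfig

        cfg = NetworkConfig(
            layers=(
                LayerSpec("conv", 3, neuron=NeuronParams(1.0, INF_THRESHOLD), bntt=False),
                LayerSpec("gap"),
                LayerSpec("linear", 2, neuron=NeuronParams(1.0, INF_THRESHOLD)),
            ),
            total_timesteps=6,
            num_classes=2,
            input_shape=(1, 12, 12),
        )
        net = SpikingNetwork(cfg, np.random.default_rng(8))
        raster = (np.random.default_rng(9).random((6, 2, 1, 12, 12)) < 0.4).astype(float)
        from spikemap import _layers

        drives = sum(
            _layers.conv2d(raster[t], net.weights["conv0.weight"]) for t in range(6)
        )
        out = net.forward(raster, keep_cache=True)
        final_u = out["cache"]["u"][0][-1]
        assert np.allclose(final_u, drives, atol=1e-9)


def test_config_roundtrip():
    cfg = standard_config(timesteps=9, num_classes=5, channels=(4, 8, 8))
    d = config_to_dict(cfg)
    back = config_from_dict(d)
    assert back == cfg


def test_config_validation():
    from spikemap.snn_core import LayerSpec, NetworkConfig

    with pytest.raises(ValueError, match="linear"):
        NetworkConfig((LayerSpec("conv", 4),), 5, 2, (1, 8, 8))
    with pytest.raises(ValueError):
        standard_config(timesteps=0)
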