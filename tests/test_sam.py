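import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikemap.sam import (
    KernelParams,
    compute_sam,
    ncs_sequence,
    ncs_step,
    normalize_heatmaps,
    resize_heatmap,
    tscs_kernel,
)


def ncs_explicit(train: np.ndarray, gamma: float, t: int) -> float:
    """Independent oracle: explicit sum over strictly-previous spike times."""
    return sum(
        math.exp(-gamma * (t - tp)) for tp in range(t) if train[tp] > 0
    )


class TestTSCSKernel:
    def test_zero_gap(self):
        for g in (0.0, 0.3, 5.0):
            assert tscs_kernel(4, 4, KernelParams(g)) == 1.0

    def test_direct_evaluation(self):
        assert tscs_kernel(5, 3, KernelParams(0.5)) == pytest.approx(
            math.exp(-1.0), abs=1e-12
        )

    def test_flat_kernel(self):
        assert tscs_kernel(9, 1, KernelParams(0.0)) == 1.0

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            KernelParams(-0.1)

    def test_future_spike_rejected(self):
        with pytest.raises(ValueError):
            tscs_kernel(3, 5, KernelParams(0.5))


class TestNCS:
    def test_silent_neuron(self):
        train = np.zeros(10)
        ncs = ncs_sequence(train, KernelParams(0.7))
        assert np.allclose(ncs, 0.0)

    def test_two_spikes_log2_kernel(self):
        # oracle: spikes at steps 1,2 seen from t=3 with gamma=ln 2
        train = np.array([0, 1, 1, 0])
        g = math.log(2.0)
        ncs = ncs_sequence(train, KernelParams(g))
        assert ncs[3] == pytest.approx(0.25 + 0.5, abs=1e-12)
        assert ncs[3] == pytest.approx(ncs_explicit(train, g, 3), abs=1e-12)

    def test_flat_kernel_counts_spikes(self):
        train = np.array([0, 1, 1, 0, 1, 0])
        ncs = ncs_sequence(train, KernelParams(0.0))
        assert ncs[5] == 3.0

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            ncs_step(np.zeros(3), np.array([0.0, 0.5, 1.0]), KernelParams(0.1))

    def test_incremental_matches_explicit_sum(self):
        # 200 random trains x random gamma, equality within 1e-9
        rng = np.random.default_rng(123)
        for _ in range(200):
            T = int(rng.integers(2, 65))
            train = (rng.random(T) < rng.uniform(0.1, 0.9)).astype(float)
            gamma = float(rng.uniform(0.0, 2.0))
            ncs = ncs_sequence(train, KernelParams(gamma))
            for t in range(T):
                assert abs(ncs[t] - ncs_explicit(train, gamma, t)) < 1e-9

    def test_upper_bound_geometric_sum(self):
        rng = np.random.default_rng(5)
        gamma = 0.3
        train = (rng.random(40) < 0.8).astype(float)
        ncs = ncs_sequence(train, KernelParams(gamma))
        for t in range(40):
            bound = sum(math.exp(-gamma * j) for j in range(1, t + 1))
            assert ncs[t] <= bound + 1e-12
        # tight when every step spikes
        full = ncs_sequence(np.ones(40), KernelParams(gamma))
        assert full[39] == pytest.approx(
            sum(math.exp(-gamma * j) for j in range(1, 40)), abs=1e-9
        )

    def test_large_gamma_only_previous_step_matters(self):
        rng = np.random.default_rng(6)
        train = (rng.random(30) < 0.5).astype(float)
        gamma = 40.0
        ncs = ncs_sequence(train, KernelParams(gamma))
        for t in range(1, 30):
            # residual history terms are O(exp(-2*gamma))
            assert ncs[t] == pytest.approx(
                math.exp(-gamma) * train[t - 1], rel=1e-6, abs=math.exp(-1.5 * gamma)
            )

    @given(
        st.lists(st.integers(0, 1), min_size=2, max_size=48),
        st.floats(0.0, 2.0, allow_nan=False),
    )
    @settings(max_examples=60, deadline=None)
    def test_property_incremental_equals_set_sum(self, bits, gamma):
        train = np.array(bits, dtype=float)
        ncs = ncs_sequence(train, KernelParams(gamma))
        t = len(bits) - 1
        assert ncs[t] == pytest.approx(ncs_explicit(train, gamma, t), abs=1e-9)


class TestComputeSAM:
    def test_zero_raster(self):
        raster = np.zeros((5, 2, 3, 3))
        assert np.allclose(compute_sam(raster, KernelParams(0.4)), 0.0)

    def test_hand_trace_single_pixel(self):
        # train [1,1,0,1], gamma=0 -> maps [0,1,0,2]
        raster = np.array([1, 1, 0, 1], dtype=float).reshape(4, 1, 1, 1)
        maps = compute_sam(raster, KernelParams(0.0))
        assert np.allclose(maps.ravel(), [0.0, 1.0, 0.0, 2.0])

    def test_channel_additivity(self):
        rng = np.random.default_rng(8)
        single = (rng.random((6, 1, 4, 4)) < 0.5).astype(float)
        double = np.concatenate([single, single], axis=1)
        m1 = compute_sam(single, KernelParams(0.3))
        m2 = compute_sam(double, KernelParams(0.3))
        assert np.allclose(m2, 2.0 * m1)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            compute_sam(np.zeros((0, 1, 2, 2)), KernelParams(0.1))
        with pytest.raises(ValueError, match="binary"):
            compute_sam(np.full((3, 1, 2, 2), 0.5), KernelParams(0.1))

    def test_label_free_forward_only(self):
        # consumes only the recorded raster: no weights, labels or gradients
        import inspect

        from spikemap.sam import compute_sam as f

        sig = inspect.signature(f)
        assert set(sig.parameters) == {"raster", "params"}


class TestNormalize:
    def test_global_max_becomes_one(self):
        seq = np.array([[[0.0, 1.0]], [[2.0, 0.5]]])
        out = normalize_heatmaps(seq)
        assert out.max() == 1.0
        assert np.allclose(out, seq / 2.0)

    def test_zero_guard(self):
        seq = np.zeros((3, 2, 2))
        out = normalize_heatmaps(seq)
        assert np.allclose(out, 0.0)

    def test_order_preserved(self):
        rng = np.random.default_rng(9)
        seq = rng.random((4, 5, 5))
        out = normalize_heatmaps(seq)
        assert np.array_equal(np.argsort(seq.ravel()), np.argsort(out.ravel()))

    def test_per_step_mode(self):
        seq = np.array([[[0.0, 2.0]], [[0.0, 4.0]]])
        out = normalize_heatmaps(seq, per_step=True)
        assert np.allclose(out, [[[0.0, 1.0]], [[0.0, 1.0]]])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            normalize_heatmaps(np.array([[[-0.1]]]))


class TestResize:
    def test_identity(self):
        m = np.random.default_rng(1).random((5, 7))
        assert np.array_equal(resize_heatmap(m, 5, 7), m)

    def test_constant_stays_constant(self):
        m = np.full((4, 4), 0.37)
        out = resize_heatmap(m, 9, 11)
        assert np.allclose(out, 0.37)

    def test_bounds_within_input_range(self):
        m = np.random.default_rng(2).random((6, 6))
        out = resize_heatmap(m, 13, 13)
        assert out.min() >= m.min() - 1e-12 and out.max() <= m.max() + 1e-12

    def test_peak_maps_to_source_block(self):
        m = np.zeros((4, 4))
        m[1, 2] = 1.0
        out = resize_heatmap(m, 8, 8)
        r, c = np.unravel_index(out.argmax(), out.shape)
        # corner-aligned: source (1,2) maps to (1*7/3, 2*7/3) = (2.33, 4.67)
        assert abs(r - 1 * 7 / 3) <= 1.0 and abs(c - 2 * 7 / 3) <= 1.0

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            resize_heatmap(np.zeros((3, 3)), 0, 5)
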