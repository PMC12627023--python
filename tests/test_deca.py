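"""Channel-attention tests, including the independent loop oracle."""

import math

import numpy as np
import pytest

from cadffnet import DECA, DecaParams, adaptive_kernel_size, deca_forward
from cadffnet import nn


# -- independent oracle: plain Python loops, written against the equations --

def deca_oracle(Ff, Fb, weights):
    H, W, C = Ff.shape
    K = len(weights)
    half = (K - 1) // 2
    # element-wise fusion, then per-channel spatial average
    desc = [0.0] * C
    for c in range(C):
        acc = 0.0
        for i in range(H):
            for j in range(W):
                acc += Ff[i, j, c] + Fb[i, j, c]
        desc[c] = acc / (H * W)
    # 1-D conv over channels, zero padded, no bias; then sigmoid
    w = [0.0] * C
    for c in range(C):
        acc = 0.0
        for t in range(K):
            src = c + t - half
            if 0 <= src < C:
                acc += weights[t] * desc[src]
        w[c] = 1.0 / (1.0 + math.exp(-acc))
    Ffh = np.empty_like(Ff)
    Fbh = np.empty_like(Fb)
    for c in range(C):
        for i in range(H):
            for j in range(W):
                Ffh[i, j, c] = w[c] * Ff[i, j, c]
                Fbh[i, j, c] = w[c] * Fb[i, j, c]
    return Ffh, Fbh, np.array(w)


def brute_force_kernel_size(C, gamma=2, b=1):
    """Smallest odd integer >= trunc((log2 C + b) / gamma), floored at 1."""
    t = int((math.log2(C) + b) / gamma)
    for k in range(max(t, 1), t + 3):
        if k % 2 == 1 and k >= t:
            return k
    raise AssertionError


class TestAdaptiveKernelSize:
    @pytest.mark.parametrize("C,expected", [
        (2, 1), (64, 3), (128, 5), (256, 5), (512, 5),
    ])
    def test_documented_values(self, C, expected):
        assert adaptive_kernel_size(C) == expected

    @pytest.mark.parametrize("C", list(range(1, 2050, 7)))
    def test_matches_brute_force(self, C):
        assert adaptive_kernel_size(C) == brute_force_kernel_size(C)

    def test_always_odd_and_positive(self):
        for C in range(1, 4097):
            k = adaptive_kernel_size(C)
            assert k >= 1 and k % 2 == 1

    def test_rejects_bad_channel_count(self):
        with pytest.raises(ValueError):
            adaptive_kernel_size(0)


def _random_params(C, rng):
    k = adaptive_kernel_size(C)
    return DecaParams(conv_weights=rng.normal(size=k))


class TestDecaForward:
    def test_zero_inputs_give_half_weights_zero_outputs(self, rng):
        Ff = np.zeros((3, 3, 4))
        Ffh, Fbh, w = deca_forward(Ff, Ff, _random_params(4, rng))
        np.testing.assert_allclose(w, 0.5)
        np.testing.assert_array_equal(Ffh, 0.0)
        np.testing.assert_array_equal(Fbh, 0.0)

    def test_zero_conv_weights_halve_inputs(self, rng):
        Ff = rng.normal(size=(2, 3, 4))
        Fb = rng.normal(size=(2, 3, 4))
        params = DecaParams(conv_weights=np.zeros(adaptive_kernel_size(4)))
        Ffh, Fbh, w = deca_forward(Ff, Fb, params)
        np.testing.assert_allclose(w, 0.5)
        np.testing.assert_allclose(Ffh, Ff / 2)
        np.testing.assert_allclose(Fbh, Fb / 2)

    def test_k1_identity_kernel_matches_oracle(self, rng):
        Ff = rng.normal(size=(3, 3, 2))
        Fb = rng.normal(size=(3, 3, 2))
        params = DecaParams(conv_weights=np.array([1.0]))
        got = deca_forward(Ff, Fb, params)
        want = deca_oracle(Ff, Fb, params.conv_weights)
        for g, w_ in zip(got, want):
            np.testing.assert_allclose(g, w_, atol=1e-6)

    @pytest.mark.parametrize("C", [2, 4, 8])
    def test_oracle_equivalence_random(self, C, rng):
        for trial in range(20):
            H, W = rng.integers(1, 5, size=2)
            Ff = rng.normal(size=(H, W, C))
            Fb = rng.normal(size=(H, W, C))
            params = _random_params(C, rng)
            got = deca_forward(Ff, Fb, params)
            want = deca_oracle(Ff, Fb, params.conv_weights)
            for g, w_ in zip(got, want):
                np.testing.assert_allclose(g, w_, atol=1e-6)

    def test_weights_strictly_in_unit_interval(self, rng):
        Ff = rng.normal(size=(4, 4, 8)) * 10
        Fb = rng.normal(size=(4, 4, 8)) * 10
        _, _, w = deca_forward(Ff, Fb, _random_params(8, rng))
        assert np.all(w > 0.0) and np.all(w < 1.0)

    def test_outputs_bounded_by_inputs(self, rng):
        Ff = rng.normal(size=(3, 3, 4))
        Fb = rng.normal(size=(3, 3, 4))
        Ffh, Fbh, _ = deca_forward(Ff, Fb, _random_params(4, rng))
        assert np.all(np.abs(Ffh) <= np.abs(Ff) + 1e-12)
        assert np.all(np.abs(Fbh) <= np.abs(Fb) + 1e-12)

    def test_swap_symmetry(self, rng):
        Ff = rng.normal(size=(2, 2, 4))
        Fb = rng.normal(size=(2, 2, 4))
        params = _random_params(4, rng)
        Ffh, Fbh, w = deca_forward(Ff, Fb, params)
        Fbh2, Ffh2, w2 = deca_forward(Fb, Ff, params)
        np.testing.assert_allclose(w, w2)
        np.testing.assert_allclose(Ffh, Ffh2)
        np.testing.assert_allclose(Fbh, Fbh2)

    def test_shared_modulation(self, rng):
        Ff = rng.uniform(1, 2, size=(2, 2, 4))
        Fb = rng.uniform(1, 2, size=(2, 2, 4))
        Ffh, Fbh, _ = deca_forward(Ff, Fb, _random_params(4, rng))
        np.testing.assert_allclose(Ffh / Ff, Fbh / Fb, atol=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            deca_forward(np.zeros((2, 2, 4)), np.zeros((2, 3, 4)),
                         _random_params(4, rng))

    def test_wrong_kernel_rejected(self):
        params = DecaParams(conv_weights=np.ones(5))  # C=4 needs K=3
        with pytest.raises(ValueError, match="adaptive"):
            deca_forward(np.zeros((2, 2, 4)), np.zeros((2, 2, 4)), params)


class TestDecaModule:
    """The trainable NCHW module must agree with the functional op."""

    def test_matches_functional(self, rng):
        with nn.default_dtype(np.float64):
            mod = DECA(8, rng=rng)
        Ff = rng.normal(size=(2, 8, 3, 3))
        Fb = rng.normal(size=(2, 8, 3, 3))
        Ffh, Fbh = mod.forward(Ff, Fb)
        params = DecaParams(conv_weights=mod.conv.weight.data)
        for n in range(2):
            eF, eB, _ = deca_forward(Ff[n].transpose(1, 2, 0),
                                     Fb[n].transpose(1, 2, 0), params)
            np.testing.assert_allclose(Ffh[n].transpose(1, 2, 0), eF, atol=1e-10)
            np.testing.assert_allclose(Fbh[n].transpose(1, 2, 0), eB, atol=1e-10)

    def test_gradients_match_finite_differences(self, rng):
        with nn.default_dtype(np.float64):
            mod = DECA(4, rng=rng)
        Ff = rng.normal(size=(2, 4, 2, 2))
        Fb = rng.normal(size=(2, 4, 2, 2))
        dFfh = rng.normal(size=Ff.shape)
        dFbh = rng.normal(size=Fb.shape)

        def loss():
            a, b = mod.forward(Ff, Fb)
            return float(np.sum(a * dFfh) + np.sum(b * dFbh))

        mod.zero_grad()
        mod.forward(Ff, Fb)
        dFf, dFb = mod.backward(dFfh.copy(), dFbh.copy())

        eps = 1e-6
        for arr, grad in ((Ff, dFf), (Fb, dFb), (mod.conv.weight.data,
                                                 mod.conv.weight.grad)):
            flat = arr.ravel()
            gflat = np.asarray(grad).ravel()
            idx = rng.choice(flat.size, size=min(10, flat.size), replace=False)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                hi = loss()
                flat[i] = orig - eps
                lo = loss()
                flat[i] = orig
                assert gflat[i] == pytest.approx((hi - lo) / (2 * eps), abs=1e-5)
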