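"""Multi-scale fusion tests, including an independent oracle.

The oracle routes the two scale convolutions through
``scipy.signal.correlate2d`` per channel pair and evaluates everything else
with explicit loops — a code path fully disjoint from the im2col module.
"""

import numpy as np
import pytest
from scipy.signal import correlate2d

from cadffnet import MSCFF, MscffParams, branch_weights, mscff_forward
from cadffnet import nn
from cadffnet.mscff import random_mscff_params


def _scale_branches(Ff, Fb, p: MscffParams):
    """Y, Y1, Y2 computed via scipy correlate2d + explicit loops."""
    H, W, C = Ff.shape
    c2 = 2 * C
    Y = np.concatenate([Ff, Fb], axis=2)

    def conv_bn_act(weights, bn):
        co = weights.shape[0]
        out = np.zeros((H, W, co))
        for o in range(co):
            acc = np.zeros((H, W))
            for ci in range(c2):
                acc += correlate2d(Y[:, :, ci], weights[o, ci], mode="same")
            out[:, :, o] = acc
        gamma, beta, mean, var = bn
        for o in range(co):
            out[:, :, o] = gamma[o] * (out[:, :, o] - mean[o]) / np.sqrt(
                var[o] + p.eps) + beta[o]
        return np.where(out > 0, out, p.leaky_slope * out)

    return Y, conv_bn_act(p.conv3_w, p.bn3), conv_bn_act(p.conv5_w, p.bn5)


def mscff_oracle(Ff, Fb, p: MscffParams):
    H, W, C = Ff.shape
    c2 = 2 * C
    Y, Y1, Y2 = _scale_branches(Ff, Fb, p)
    Yhat = np.concatenate([Y1, Y2], axis=2)
    S = [Yhat[:, :, c].mean() for c in range(4 * C)]
    hid = p.w1.shape[0]
    h = [max(sum(p.w1[i, j] * S[j] for j in range(4 * C)) + p.b1[i], 0.0)
         for i in range(hid)]
    S_prime = np.array([sum(p.w2[i, j] * h[j] for j in range(hid)) + p.b2[i]
                        for i in range(4 * C)])
    S1, S2 = branch_weights(S_prime, p.softmax_scope)
    O = np.empty((H, W, c2))
    for c in range(c2):
        O[:, :, c] = Y[:, :, c] + S1[c] * Y1[:, :, c] + S2[c] * Y2[:, :, c]
    return O


class TestBranchWeights:
    def test_zero_logits_split_evenly(self):
        S1, S2 = branch_weights(np.zeros(8))
        np.testing.assert_allclose(S1, 0.5)
        np.testing.assert_allclose(S2, 0.5)

    def test_closed_form_ln3(self):
        S1, S2 = branch_weights(np.array([np.log(3.0), 0.0]))
        assert S1[0] == pytest.approx(0.75)
        assert S2[0] == pytest.approx(0.25)

    def test_saturation(self):
        S1, S2 = branch_weights(np.array([60.0, 0.0, 0.0, 0.0]))
        assert S1[0] == pytest.approx(1.0, abs=1e-12)
        assert S2[0] == pytest.approx(0.0, abs=1e-12)

    def test_pairwise_normalization_exact(self, rng):
        S_prime = rng.normal(size=32) * 5
        S1, S2 = branch_weights(S_prime)
        np.testing.assert_array_equal(S1 + S2, np.ones(16))

    def test_entries_in_open_interval(self, rng):
        S1, S2 = branch_weights(rng.normal(size=16))
        assert np.all((S1 > 0) & (S1 < 1)) and np.all((S2 > 0) & (S2 < 1))

    def test_odd_length_rejected(self):
        with pytest.raises(ValueError):
            branch_weights(np.zeros(5))

    def test_full_scope_sums_to_one_overall(self, rng):
        S1, S2 = branch_weights(rng.normal(size=12), scope="full")
        assert S1.sum() + S2.sum() == pytest.approx(1.0)


class TestMscffForward:
    @pytest.mark.parametrize("C", [2, 4, 8])
    def test_oracle_equivalence_random(self, C, rng):
        for trial in range(8):
            H, W = rng.integers(1, 5, size=2)
            Ff = rng.normal(size=(H, W, C))
            Fb = rng.normal(size=(H, W, C))
            p = random_mscff_params(C, r=4, rng=rng)
            got = mscff_forward(Ff, Fb, p)
            np.testing.assert_allclose(got, mscff_oracle(Ff, Fb, p), atol=1e-6)

    def test_channel_arithmetic(self, rng):
        # C channels in each branch -> 2C out, spatial size untouched
        Ff = rng.normal(size=(5, 3, 4))
        Fb = rng.normal(size=(5, 3, 4))
        out = mscff_forward(Ff, Fb, random_mscff_params(4, r=4, rng=rng))
        assert out.shape == (5, 3, 8)

    def test_zero_squeeze_gives_mean_of_scales(self, rng):
        """w1=w2=b=0 => S' = 0 => S1 = S2 = 1/2 => O = Y + (Y1+Y2)/2."""
        C = 4
        p = random_mscff_params(C, r=4, rng=rng)
        p.w1[...] = 0.0
        p.b1[...] = 0.0
        p.w2[...] = 0.0
        p.b2[...] = 0.0
        Ff = rng.normal(size=(3, 3, C))
        Fb = rng.normal(size=(3, 3, C))
        got = mscff_forward(Ff, Fb, p)
        Y, Y1, Y2 = _scale_branches(Ff, Fb, p)
        np.testing.assert_allclose(got, Y + 0.5 * (Y1 + Y2), atol=1e-8)

    def test_residual_is_convex_combination(self, rng):
        """O - Y lies channel-wise between min(Y1, Y2) and max(Y1, Y2)."""
        C = 4
        p = random_mscff_params(C, r=4, rng=rng)
        Ff = rng.normal(size=(3, 3, C))
        Fb = rng.normal(size=(3, 3, C))
        O = mscff_forward(Ff, Fb, p)
        Y, Y1, Y2 = _scale_branches(Ff, Fb, p)
        resid = O - Y
        assert np.all(resid >= np.minimum(Y1, Y2) - 1e-8)
        assert np.all(resid <= np.maximum(Y1, Y2) + 1e-8)

    def test_shape_mismatch_rejected(self, rng):
        p = random_mscff_params(2, r=4, rng=rng)
        with pytest.raises(ValueError):
            mscff_forward(np.zeros((2, 2, 2)), np.zeros((2, 3, 2)), p)

    def test_indivisible_reduction_rejected(self, rng):
        with pytest.raises(ValueError):
            random_mscff_params(2, r=3, rng=rng)


class TestMscffModule:
    def test_shapes_preserved(self, rng):
        with nn.default_dtype(np.float64):
            mod = MSCFF(4, r=4, rng=rng)
        Ff = rng.normal(size=(2, 4, 3, 3))
        Fb = rng.normal(size=(2, 4, 3, 3))
        out = mod.forward(Ff, Fb)
        assert out.shape == (2, 8, 3, 3)

    def test_eval_mode_matches_functional(self, rng):
        with nn.default_dtype(np.float64):
            mod = MSCFF(4, r=4, rng=rng)
        mod.eval()
        Ff = rng.normal(size=(1, 4, 3, 3))
        Fb = rng.normal(size=(1, 4, 3, 3))
        out = mod.forward(Ff, Fb)
        p = MscffParams(
            conv3_w=mod.conv3.weight.data.reshape(8, 8, 3, 3),
            bn3=(mod.bn3.gamma.data, mod.bn3.beta.data,
                 mod.bn3.running_mean, mod.bn3.running_var),
            conv5_w=mod.conv5.weight.data.reshape(8, 8, 5, 5),
            bn5=(mod.bn5.gamma.data, mod.bn5.beta.data,
                 mod.bn5.running_mean, mod.bn5.running_var),
            w1=mod.fc1.weight.data, b1=mod.fc1.bias.data,
            w2=mod.fc2.weight.data, b2=mod.fc2.bias.data, r=4,
        )
        expected = mscff_forward(Ff[0].transpose(1, 2, 0),
                                 Fb[0].transpose(1, 2, 0), p)
        np.testing.assert_allclose(out[0].transpose(1, 2, 0), expected,
                                   atol=1e-8)

    def test_gradients_match_finite_differences(self, rng):
        with nn.default_dtype(np.float64):
            mod = MSCFF(2, r=4, rng=rng)
        mod.eval()  # frozen BN keeps the fd check exact and cheap
        Ff = rng.normal(size=(2, 2, 3, 3))
        Fb = rng.normal(size=(2, 2, 3, 3))
        dout = rng.normal(size=(2, 4, 3, 3))

        def loss():
            return float(np.sum(mod.forward(Ff, Fb) * dout))

        mod.zero_grad()
        mod.forward(Ff, Fb)
        dFf, dFb = mod.backward(dout.copy())

        eps = 1e-6
        checks = [(Ff, dFf), (Fb, dFb)]
        checks += [(p.data, p.grad) for _, p in mod.named_parameters()]
        rng2 = np.random.default_rng(1)
        for arr, grad in checks:
            flat = arr.ravel()
            gflat = np.asarray(grad).ravel()
            idx = rng2.choice(flat.size, size=min(6, flat.size), replace=False)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                hi = loss()
                flat[i] = orig - eps
                lo = loss()
                flat[i] = orig
                assert gflat[i] == pytest.approx((hi - lo) / (2 * eps),
                                                 rel=1e-4, abs=1e-6)
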