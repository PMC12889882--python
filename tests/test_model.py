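"""Model core: the four attention operators against brute-force oracles,
masked-softmax properties, exact mask invariance, inference determinism,
bidirectionality, and backprop vs finite differences."""

import numpy as np
import pytest

from airsurf import (ModelConfig, PM25SequenceModel, attended_output,
                     attention_scores, attention_weights, context_vector)
from airsurf.nn import Tensor
from airsurf.nn.layers import BiLSTMLayer


class TestAttentionOps:
    def test_identical_states_give_equal_scores(self, rng):
        h = rng.normal(size=4)
        all_h = np.tile(h, (21, 1))
        s = attention_scores(h, all_h, np.eye(4))
        np.testing.assert_allclose(s, np.dot(h, h))

    def test_orthogonal_state_scores_zero(self):
        s = attention_scores(np.array([1.0, 0.0]),
                             np.array([[0.0, 1.0]]), np.eye(2))
        assert s[0] == 0.0

    def test_bilinear_matches_double_loop(self, rng):
        """Brute-force oracle: explicit sum_ij h_t[i] W[i,j] h_s[j]."""
        h_t = rng.normal(size=4)
        h_all = rng.normal(size=(21, 4))
        W = rng.normal(size=(4, 4))
        got = attention_scores(h_t, h_all, W)
        expect = np.array([
            sum(h_t[i] * W[i, j] * h_s[j]
                for i in range(4) for j in range(4))
            for h_s in h_all])
        np.testing.assert_allclose(got, expect, atol=1e-8)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            attention_scores(rng.normal(size=4), rng.normal(size=(21, 4)),
                             rng.normal(size=(3, 3)))

    def test_uniform_softmax(self):
        a = attention_weights(np.zeros(21))
        np.testing.assert_allclose(a, 1 / 21)

    def test_closed_form_two_step_softmax(self):
        a = attention_weights(np.array([np.log(2.0), 0.0]))
        np.testing.assert_allclose(a, [2 / 3, 1 / 3])

    def test_softmax_shift_invariance(self, rng):
        s = rng.normal(size=21)
        np.testing.assert_allclose(attention_weights(s),
                                   attention_weights(s + 123.456), atol=1e-12)

    def test_masked_weights_zero_and_sum_one(self, rng):
        mask = np.zeros(21, bool)
        mask[[2, 5, 19]] = True
        a = attention_weights(rng.normal(size=21), mask)
        assert a[mask].sum() == 0.0
        assert a.sum() == pytest.approx(1.0)
        assert (a >= 0).all()

    def test_all_masked_raises(self):
        with pytest.raises(ValueError):
            attention_weights(np.zeros(3), np.ones(3, bool))

    def test_context_one_hot_picks_state(self, rng):
        h_all = rng.normal(size=(21, 4))
        a = np.zeros(21)
        a[7] = 1.0
        np.testing.assert_allclose(context_vector(a, h_all), h_all[7])

    def test_context_matches_weighted_sum_loop(self, rng):
        h_all = rng.normal(size=(21, 4))
        a = rng.dirichlet(np.ones(21))
        expect = sum(a[s] * h_all[s] for s in range(21))
        np.testing.assert_allclose(context_vector(a, h_all), expect, atol=1e-8)

    def test_attended_output_zero_map_and_bounds(self, rng):
        c, h = rng.normal(size=4), rng.normal(size=4)
        assert (attended_output(c, h, np.zeros((4, 8))) == 0.0).all()
        out = attended_output(c, h, rng.normal(size=(4, 8)))
        assert (np.abs(out) < 1.0).all()
        # tanh saturates to exactly +-1.0 in float64 at extreme inputs
        sat = attended_output(c * 1e6, h * 1e6, rng.normal(size=(4, 8)))
        assert (np.abs(sat) <= 1.0).all()

    def test_attended_output_matches_explicit_oracle(self, rng):
        c, h = rng.normal(size=4), rng.normal(size=4)
        W_c = rng.normal(size=(4, 8))
        expect = np.tanh(W_c @ np.concatenate([c, h]))
        np.testing.assert_allclose(attended_output(c, h, W_c), expect,
                                   atol=1e-8)


@pytest.fixture(scope="module")
def tiny_model():
    return PM25SequenceModel(ModelConfig(layer_widths=(8, 8), n_features=5,
                                         seed=1))


class TestForward:
    def test_inference_deterministic(self, tiny_model, rng):
        X = rng.normal(size=(3, 21, 5))
        p1 = tiny_model.predict(X)
        p2 = tiny_model.predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_training_dropout_is_stochastic_but_seeded(self, rng):
        X = rng.normal(size=(3, 21, 5))
        m1 = PM25SequenceModel(ModelConfig(layer_widths=(8, 8), n_features=5,
                                           seed=1))
        a, _ = m1.forward(X, training=True)
        b, _ = m1.forward(X, training=True)
        assert not np.array_equal(a.data, b.data)  # fresh dropout draws
        m2 = PM25SequenceModel(ModelConfig(layer_widths=(8, 8), n_features=5,
                                           seed=1))
        c, _ = m2.forward(X, training=True)
        np.testing.assert_array_equal(a.data, c.data)  # same seed, same draws

    def test_mask_invariance_is_exact(self, tiny_model, rng):
        """Perturbing every stored value of masked timesteps changes the
        output by exactly zero."""
        X = rng.normal(size=(20, 21, 5))
        mask = rng.random((20, 21)) < 0.3
        mask[:, -1] = False  # keep the query step observed
        X2 = X.copy()
        X2[mask] = rng.normal(size=(int(mask.sum()), 5)) * 1e6
        np.testing.assert_array_equal(tiny_model.predict(X, mask),
                                      tiny_model.predict(X2, mask))

    def test_masked_steps_get_zero_attention(self, tiny_model, rng):
        x = rng.normal(size=(21, 5))
        mask = np.zeros(21, bool)
        mask[4:9] = True
        _, trace = tiny_model.forward_one(x, mask)
        assert (trace.alpha[4:9] == 0.0).all()
        assert trace.alpha.sum() == pytest.approx(1.0)
        assert (trace.alpha >= 0).all()

    def test_all_masked_sample_raises(self, tiny_model, rng):
        X = rng.normal(size=(1, 21, 5))
        with pytest.raises(ValueError):
            tiny_model.forward(X, np.ones((1, 21), bool))

    def test_single_sample_trace_matches_batch_path(self, tiny_model, rng):
        x = rng.normal(size=(21, 5))
        y_one, trace = tiny_model.forward_one(x)
        y_batch = tiny_model.predict(x[None])[0]
        assert y_one == pytest.approx(y_batch, abs=1e-9)
        assert trace.h_hat.shape == (21, tiny_model.hidden_dim)

    def test_unidirectional_halves_state_width(self):
        uni = PM25SequenceModel(ModelConfig(
            layer_widths=(8, 8), n_features=5, bidirectional=False,
            width_interpretation="per_direction", seed=0))
        assert uni.hidden_dim == 8
        bi = PM25SequenceModel(ModelConfig(layer_widths=(8, 8), n_features=5,
                                           seed=0))
        assert bi.hidden_dim == 8  # total interpretation: 4 per direction


def test_bidirectional_layer_reversal_identity(rng):
    """Swapping direction weights and reversing the sequence yields the
    block-swapped, time-reversed hidden states — the defining symmetry of
    a bidirectional recurrence."""
    xs_data = [rng.normal(size=(2, 3)) for _ in range(7)]
    keep = np.ones((7, 2, 1))
    layer = BiLSTMLayer(3, 4, np.random.default_rng(0))
    twin = BiLSTMLayer(3, 4, np.random.default_rng(1))
    # tie twin's forward to layer's backward and vice versa
    for a, b in ((twin.fwd, layer.bwd), (twin.bwd, layer.fwd)):
        a.Wx.data = b.Wx.data.copy()
        a.Wh.data = b.Wh.data.copy()
        a.b.data = b.b.data.copy()
    out = layer([Tensor(x) for x in xs_data], keep)
    out_rev = twin([Tensor(x) for x in xs_data[::-1]], keep)
    for t in range(7):
        fwd, bwd = np.split(out[t].data, 2, axis=1)
        fwd_r, bwd_r = np.split(out_rev[6 - t].data, 2, axis=1)
        np.testing.assert_allclose(fwd, bwd_r, atol=1e-12)
        np.testing.assert_allclose(bwd, fwd_r, atol=1e-12)


def test_backprop_matches_finite_differences_on_toy_model(rng):
    """Finite-difference gradient of the scalar output w.r.t. the
    attention matrix W matches backprop to 1e-4 relative."""
    m = PM25SequenceModel(ModelConfig(layer_widths=(4, 4), n_features=3,
                                      seed=0))
    X = rng.normal(size=(2, 21, 3))
    mask = np.zeros((2, 21), bool)
    mask[0, 5:8] = True

    def scalar():
        p, _ = m.forward(X, mask)
        return p.sum()

    out = scalar()
    out.backward()
    g = m.W_att.grad.copy()
    eps = 1e-6
    for idx in [(0, 0), (1, 3), (2, 2), (3, 1)]:
        m.W_att.data[idx] += eps
        f1 = float(scalar().data)
        m.W_att.data[idx] -= 2 * eps
        f2 = float(scalar().data)
        m.W_att.data[idx] += eps
        fd = (f1 - f2) / (2 * eps)
        assert g[idx] == pytest.approx(fd, rel=1e-4, abs=1e-9)
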