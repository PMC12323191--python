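"""Attention arithmetic, encoder behaviour, and trunk gradient correctness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from expfusion.nn import (
    AttentionConfig,
    FusionTrunk,
    scaled_dot_attention,
    sinusoidal_positions,
    train_trunk,
)


class TestScaledDotAttention:
    def test_single_key_returns_value_row(self):
        out = scaled_dot_attention([[3.0, -1.0]], [[0.5, 0.5]], [[7.0]])
        assert out[0, 0] == pytest.approx(7.0)

    def test_hand_computed_two_key_case(self):
        """Q=[[1,0]], K=I, V=[[1],[0]]: weights softmax([1,0]/sqrt(2))."""
        out = scaled_dot_attention([[1.0, 0.0]], [[1.0, 0.0], [0.0, 1.0]], [[1.0], [0.0]])
        e = np.exp(1 / np.sqrt(2))
        w0 = e / (e + 1)
        assert w0 == pytest.approx(0.6698, abs=1e-4)
        assert out[0, 0] == pytest.approx(w0, abs=1e-10)

    def test_shift_invariance_of_scores(self, rng):
        """Adding a constant to every score in a row leaves the output unchanged."""
        Q, K, V = rng.normal(size=(3, 4)), rng.normal(size=(4, 4)), rng.normal(size=(4, 2))
        c = 2.7
        # query offset u with K u = c*1 shifts every score in the row by c
        u = np.linalg.solve(K, np.full(4, c * np.sqrt(4)))
        base = scaled_dot_attention(Q, K, V)
        shifted = scaled_dot_attention(Q + u, K, V)
        np.testing.assert_allclose(shifted, base, atol=1e-9)

    @given(
        Q=arrays(float, (2, 3), elements=st.floats(-5, 5)),
        K=arrays(float, (4, 3), elements=st.floats(-5, 5)),
    )
    @settings(max_examples=25, deadline=None)
    def test_rows_are_convex_weights(self, Q, K):
        V = np.eye(4)
        W = scaled_dot_attention(Q, K, V)  # rows of W are the attention weights
        assert np.all(W >= 0)
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-9)

    def test_nan_input_rejected(self):
        with pytest.raises(ValueError):
            scaled_dot_attention([[np.nan]], [[1.0]], [[1.0]])


def _toy_trunk(variant="full", n_layers=2, seed=0):
    cfg = AttentionConfig(model_dim=8, n_heads=2, n_layers=n_layers, ff_dim=16,
                          dropout=0.0, max_len=12)
    return FusionTrunk(vocab_size=9, n_tabular=3, config=cfg, variant=variant, seed=seed)


def _toy_batch(rng, B=4, L=7):
    ids = rng.integers(0, 9, size=(B, L))
    mask = np.ones((B, L))
    mask[2, 5:] = 0
    mask[3, 4:] = 0
    tab = rng.normal(size=(B, 3))
    return ids, mask, tab


class TestEncoder:
    def test_evaluation_mode_deterministic(self, rng):
        tk = _toy_trunk()
        ids, mask, tab = _toy_batch(rng)
        np.testing.assert_array_equal(tk.forward(ids, mask, tab), tk.forward(ids, mask, tab))

    def test_padding_tail_does_not_affect_features(self, rng):
        tk = _toy_trunk()
        ids, mask, tab = _toy_batch(rng)
        f1 = tk.features(ids, mask, tab)
        ids2 = ids.copy()
        ids2[3, 4:] = rng.integers(0, 9, size=3)  # rewrite padding-only tail
        f2 = tk.features(ids2, mask, tab)
        np.testing.assert_allclose(f1[3], f2[3], atol=1e-12)

    def test_zero_layer_pooled_equals_direct_mean_oracle(self, rng):
        tk = _toy_trunk(n_layers=0)
        ids, mask, tab = _toy_batch(rng)
        feats = tk.features(ids, mask, tab)
        d = tk.config.model_dim
        pooled = feats[:, d : 2 * d]  # [cross | pooled | tab-pad]
        pos = sinusoidal_positions(tk.config.max_len, d)
        for b in range(ids.shape[0]):
            rowmask = mask[b] > 0
            expect = (tk.embedding[ids[b]] + pos[: ids.shape[1]])[rowmask].mean(axis=0)
            np.testing.assert_allclose(pooled[b], expect, atol=1e-12)

    def test_truncation_warns(self, rng):
        tk = _toy_trunk()
        ids = rng.integers(0, 9, size=(1, 20))
        with pytest.warns(UserWarning, match="truncat"):
            tk.features(ids, np.ones((1, 20)), rng.normal(size=(1, 3)))

    def test_cross_attention_matches_functional_form(self, rng):
        """The fusion cross-attention equals scaled_dot_attention called with
        the projected query and the trunk's K/V projections."""
        tk = _toy_trunk()
        ids, mask, tab = _toy_batch(rng)
        d = tk.config.model_dim
        feats = tk.features(ids, mask, tab)
        cross = feats[:, :d]
        x = tk._cache["x"]
        q = tk.cross_q.forward(tk.tab_proj.forward(tab))[:, None, :]
        K = tk.cross_k.forward(x)
        V = tk.cross_v.forward(x)
        expect = scaled_dot_attention(q, K, V, mask=mask)[:, 0, :]
        np.testing.assert_allclose(cross, expect, atol=1e-10)

    def test_identical_token_states_make_cross_output_that_state(self, rng):
        tk = _toy_trunk(n_layers=0)
        L = 5
        ids = np.full((1, L), 4)  # same token everywhere -> embedding equal...
        # positions differ, so force equality by zeroing positional encoding
        tk.posenc = np.zeros_like(tk.posenc)
        mask = np.ones((1, L))
        tab = rng.normal(size=(1, 3))
        feats = tk.features(ids, mask, tab)
        d = tk.config.model_dim
        state = tk.cross_v.forward(tk.embedding[4][None, None, :])[0, 0]
        np.testing.assert_allclose(feats[0, :d], state, atol=1e-10)

    def test_fused_width_by_variant(self, rng):
        ids, mask, tab = _toy_batch(rng)
        assert _toy_trunk("full").features(ids, mask, tab).shape[1] == 24
        assert _toy_trunk("no_cross_attention").features(ids, mask, tab).shape[1] == 16

    def test_state_dict_round_trip(self, rng):
        a, b = _toy_trunk(seed=1), _toy_trunk(seed=2)
        ids, mask, tab = _toy_batch(rng)
        b.load_state_dict(a.state_dict())
        np.testing.assert_allclose(a.forward(ids, mask, tab), b.forward(ids, mask, tab))


class TestGradients:
    @pytest.mark.parametrize("variant", ["full", "no_cross_attention"])
    def test_backward_matches_finite_differences(self, variant, rng):
        tk = _toy_trunk(variant)
        ids, mask, tab = _toy_batch(rng)
        y = rng.normal(size=4)

        def loss():
            return float(np.mean((tk.forward(ids, mask, tab) - y) ** 2))

        tk.zero_grad()
        pred = tk.forward(ids, mask, tab)
        tk.backward(2.0 * (pred - y) / len(y))
        eps = 1e-6
        check = np.random.default_rng(0)
        for p, g in tk.params():
            flat, gflat = p.reshape(-1), g.reshape(-1)
            for _ in range(3):
                k = check.integers(0, flat.size)
                old = flat[k]
                flat[k] = old + eps
                lp = loss()
                flat[k] = old - eps
                lm = loss()
                flat[k] = old
                assert (lp - lm) / (2 * eps) == pytest.approx(gflat[k], abs=5e-7)

    def test_tabular_gradient_flows_through_alignment(self, rng):
        tk = _toy_trunk()
        ids, mask, tab = _toy_batch(rng)
        tk.zero_grad()
        pred = tk.forward(ids, mask, tab)
        g_tab = tk.backward(np.ones_like(pred))
        assert g_tab.shape == tab.shape
        assert np.any(g_tab != 0)


class TestTraining:
    def test_loss_decreases_and_is_deterministic(self, rng):
        ids, mask, tab = _toy_batch(rng, B=32, L=7)
        y = rng.normal(size=32)
        h1 = train_trunk(_toy_trunk(seed=3), ids, mask, tab, y, epochs=5, batch_size=8,
                         lr=1e-2, seed=7)
        h2 = train_trunk(_toy_trunk(seed=3), ids, mask, tab, y, epochs=5, batch_size=8,
                         lr=1e-2, seed=7)
        assert h1 == h2
        assert h1[-1] < h1[0]
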