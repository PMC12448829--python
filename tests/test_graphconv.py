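"""Diffusion graph convolution blocks vs brute-force expansions."""

import hashlib

import numpy as np
import pytest

from protfun.attention import sparse_topk_normalize
from protfun.autodiff import Tensor
from protfun.errors import ConfigError, DataError
from protfun.graphconv import (DiffusionConvParams, function_graph_conv,
                               function_graph_conv_adaptive_only,
                               normalize_prior, protein_graph_conv,
                               protein_graph_conv_adaptive_only)
from protfun.oracles import naive_diffusion
from protfun.protein_graph import DiffusionPair, row_normalize


def _params(roles, steps, c_in, c_out, rng=None, identity=False):
    if identity:
        weights = {r: [Tensor(np.eye(c_in)) for _ in range(steps)]
                   for r in roles}
        return DiffusionConvParams(steps=steps, weights=weights)
    rng = rng or np.random.default_rng(0)
    weights = {r: [Tensor(rng.normal(size=(c_in, c_out))) for _ in range(steps)]
               for r in roles}
    return DiffusionConvParams(steps=steps, weights=weights)


def _att(matrix):
    return sparse_topk_normalize(np.asarray(matrix, dtype=float),
                                 k=matrix.shape[0])


class TestFunctionBlock:
    def test_identity_limit(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 4, 2))
        params = DiffusionConvParams(steps=1, weights={
            "prior": [Tensor(np.eye(2))],
            "adaptive": [Tensor(np.zeros((2, 2)))]})
        out = function_graph_conv(x, np.eye(3), _att(np.full((3, 3), -60.0)),
                                  params)
        # adaptive weight zero, prior identity -> output equals input
        np.testing.assert_allclose(out.data, x, atol=1e-12)

    def test_all_zero_graphs_give_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(3, 4, 2))
        params = _params(("prior", "adaptive"), 2, 2, 2, rng)
        out = function_graph_conv(x, np.zeros((3, 3)), Tensor(np.zeros((3, 3))),
                                  params)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_power_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_f, n_p, c_in, c_out, steps = 5, 4, 3, 2, 2
        x = rng.normal(size=(n_f, n_p, c_in))
        a_f = row_normalize((rng.random((n_f, n_f)) < 0.4).astype(float))
        f_att = row_normalize(rng.random((n_f, n_f)) + 0.01)
        params = _params(("prior", "adaptive"), steps, c_in, c_out, rng)
        out = function_graph_conv(x, a_f, Tensor(f_att), params)
        expected = naive_diffusion(
            x, [a_f, f_att],
            [[w.data for w in params.weights["prior"]],
             [w.data for w in params.weights["adaptive"]]],
            steps, axis="function")
        np.testing.assert_allclose(out.data, expected, atol=1e-8)

    def test_adaptive_only_equals_zero_prior(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(4, 3, 2))
        f_att = Tensor(row_normalize(rng.random((4, 4))))
        params = _params(("prior", "adaptive"), 2, 2, 2, rng)
        full = function_graph_conv(x, np.zeros((4, 4)), f_att, params)
        adaptive = function_graph_conv_adaptive_only(x, f_att, params)
        np.testing.assert_allclose(full.data, adaptive.data, atol=1e-12)

    def test_single_step_reduces_to_single_product(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(3, 2, 2))
        f_att = row_normalize(rng.random((3, 3)))
        params = _params(("adaptive",), 1, 2, 2, rng)
        out = function_graph_conv_adaptive_only(x, Tensor(f_att), params)
        expected = np.tensordot(f_att, x, axes=(1, 0)) @ \
            params.weights["adaptive"][0].data
        np.testing.assert_allclose(out.data, expected, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        params = _params(("prior", "adaptive"), 1, 2, 2)
        with pytest.raises(DataError):
            function_graph_conv(np.zeros((4, 3, 2)), np.zeros((3, 3)),
                                Tensor(np.zeros((3, 3))), params)


class TestProteinBlock:
    def test_identity_limit(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(3, 4, 2))
        half = Tensor(0.5 * np.eye(2))
        params = DiffusionConvParams(steps=1, weights={
            "forward": [half], "backward": [half],
            "adaptive": [Tensor(np.zeros((2, 2)))]})
        diff = DiffusionPair(forward=np.eye(4), backward=np.eye(4))
        out = protein_graph_conv(x, diff, Tensor(np.zeros((4, 4))), params)
        np.testing.assert_allclose(out.data, x, atol=1e-12)

    def test_symmetric_prior_collapses_directions(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(3, 4, 2))
        adj = (rng.random((4, 4)) < 0.5).astype(float)
        adj = np.maximum(adj, adj.T)
        np.fill_diagonal(adj, 0)
        r = row_normalize(adj + np.eye(4))
        diff = DiffusionPair(forward=r, backward=r)
        shared = [Tensor(rng.normal(size=(2, 2))) for _ in range(2)]
        params = DiffusionConvParams(steps=2, weights={
            "forward": shared, "backward": shared,
            "adaptive": [Tensor(np.zeros((2, 2)))] * 2})
        out = protein_graph_conv(x, diff, Tensor(np.zeros((4, 4))), params)
        # forward and backward terms coincide: total = 2 * forward term
        single = naive_diffusion(x, [r], [[w.data for w in shared]], 2,
                                 axis="protein")
        np.testing.assert_allclose(out.data, 2 * single, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_power_sum_oracle(self, seed):
        rng = np.random.default_rng(seed + 50)
        n_f, n_p, c, steps = 3, 5, 2, 2
        x = rng.normal(size=(n_f, n_p, c))
        adj = (rng.random((n_p, n_p)) < 0.5).astype(float)
        np.fill_diagonal(adj, 0)
        r_f = row_normalize(adj + np.eye(n_p))
        r_b = row_normalize(adj.T + np.eye(n_p))
        p_att = row_normalize(rng.random((n_p, n_p)) + 0.01)
        params = _params(("forward", "backward", "adaptive"), steps, c, c, rng)
        diff = DiffusionPair(forward=r_f, backward=r_b)
        out = protein_graph_conv(x, diff, Tensor(p_att), params)
        expected = naive_diffusion(
            x, [r_f, r_b, p_att],
            [[w.data for w in params.weights[r]] for r in
             ("forward", "backward", "adaptive")],
            steps, axis="protein")
        np.testing.assert_allclose(out.data, expected, atol=1e-8)

    def test_adaptive_only_matches_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(3, 4, 2))
        p_att = row_normalize(rng.random((4, 4)))
        params = _params(("adaptive",), 2, 2, 2, rng)
        out = protein_graph_conv_adaptive_only(x, Tensor(p_att), params)
        expected = naive_diffusion(x, [p_att],
                                   [[w.data for w in params.weights["adaptive"]]],
                                   2, axis="protein")
        np.testing.assert_allclose(out.data, expected, atol=1e-8)


class TestInvariants:
    def test_priors_unchanged_by_forward_and_backward(self):
        rng = np.random.default_rng(7)
        x = Tensor(rng.normal(size=(3, 4, 2)), requires_grad=True)
        a_f = row_normalize((rng.random((3, 3)) < 0.5).astype(float))
        adj = np.maximum(*(m := (rng.random((4, 4)) < 0.5).astype(float),
                           m.T))
        np.fill_diagonal(adj, 0)
        r = row_normalize(adj + np.eye(4))
        diff = DiffusionPair(forward=r.copy(), backward=r.copy())
        checks = {name: hashlib.sha256(arr.tobytes()).hexdigest()
                  for name, arr in (("a_f", a_f), ("r_f", diff.forward),
                                    ("r_b", diff.backward))}
        params_f = _params(("prior", "adaptive"), 2, 2, 2, rng)
        params_p = _params(("forward", "backward", "adaptive"), 2, 2, 2, rng)
        out = protein_graph_conv(x, diff, Tensor(row_normalize(rng.random((4, 4)))),
                                 params_p)
        out = function_graph_conv(out, a_f, Tensor(row_normalize(rng.random((3, 3)))),
                                  params_f)
        out.sum().backward()
        after = {"a_f": hashlib.sha256(a_f.tobytes()).hexdigest(),
                 "r_f": hashlib.sha256(diff.forward.tobytes()).hexdigest(),
                 "r_b": hashlib.sha256(diff.backward.tobytes()).hexdigest()}
        assert after == checks

    def test_locality_within_n_steps(self):
        # chain graph 0-1-2-3-4, no self-loops, N=2: node 0's output
        # cannot depend on node 3 or 4
        n = 5
        chain = np.zeros((n, n))
        for i in range(n - 1):
            chain[i, i + 1] = chain[i + 1, i] = 1.0
        t = row_normalize(chain)
        diff = DiffusionPair(forward=t, backward=t)
        params = _params(("forward", "backward", "adaptive"), 2, 2, 2,
                         np.random.default_rng(8))
        rng = np.random.default_rng(9)
        x = rng.normal(size=(2, n, 2))
        base = protein_graph_conv(x, diff, Tensor(np.zeros((n, n))), params)
        far = x.copy()
        far[:, 3:, :] = 0.0
        out = protein_graph_conv(far, diff, Tensor(np.zeros((n, n))), params)
        np.testing.assert_allclose(out.data[:, 0], base.data[:, 0], atol=1e-12)
        assert not np.allclose(out.data[:, 1], base.data[:, 1])

    def test_linearity_in_x(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(3, 4, 2))
        y = rng.normal(size=(3, 4, 2))
        a_f = row_normalize(rng.random((3, 3)))
        att = Tensor(row_normalize(rng.random((3, 3))))
        params = _params(("prior", "adaptive"), 2, 2, 2, rng)
        combo = function_graph_conv(2.0 * x - 3.0 * y, a_f, att, params)
        parts = 2.0 * function_graph_conv(x, a_f, att, params).data - \
            3.0 * function_graph_conv(y, a_f, att, params).data
        np.testing.assert_allclose(combo.data, parts, atol=1e-10)

    def test_bad_step_count(self):
        with pytest.raises(ConfigError):
            DiffusionConvParams(steps=0, weights={})

    def test_prior_norm_modes(self):
        a = np.array([[0.0, 1.0], [0.0, 0.0]])
        np.testing.assert_array_equal(normalize_prior(a, "raw"), a)
        np.testing.assert_array_equal(normalize_prior(a, "row"), a)
        with pytest.raises(ConfigError):
            normalize_prior(a, "sym")
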