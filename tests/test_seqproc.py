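"""Sequence block: truncation, embedding seam, DCC, gating, fusion."""

import numpy as np
import pytest

from protfun import seqproc
from protfun.autodiff import Tensor
from protfun.errors import ConfigError, DataError, EmbeddingError
from protfun.fixtures import StubEmbedder
from protfun.oracles import naive_dcc, receptive_field_by_impulse
from protfun.seqproc import (DccLayer, SequenceBlock, dcc_layer, embed,
                             fuse_global_local, gated_multiscale_fusion,
                             pool_to_protein, preprocess_sequence,
                             receptive_field)


class TestPreprocess:
    def test_overlong_truncated_to_1000(self):
        assert len(preprocess_sequence("A" * 1500)) == 1000

    def test_boundary_1024_unchanged(self):
        seq = "A" * 1024
        assert preprocess_sequence(seq) == seq

    def test_1025_truncated(self):
        assert len(preprocess_sequence("A" * 1025)) == 1000

    def test_short_unchanged(self):
        assert preprocess_sequence("MKVLT") == "MKVLT"

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            preprocess_sequence("")

    def test_bad_characters_rejected(self):
        with pytest.raises(DataError):
            preprocess_sequence("MKB1")


class TestEmbed:
    def test_stub_shape(self):
        matrix = embed("ACD", StubEmbedder(dim=8))
        assert matrix.shape == (3, 8)

    def test_frozen_determinism(self):
        embedder = StubEmbedder(dim=8, seed=1)
        np.testing.assert_array_equal(embed("MKV", embedder),
                                      embed("MKV", embedder))

    def test_consistent_width(self):
        embedder = StubEmbedder(dim=12)
        for seq in ("A", "ACDEF", "MKVLTW"):
            assert embed(seq, embedder).shape == (len(seq), 12)

    def test_adapter_failure_carries_id(self):
        def broken(_seq):
            raise RuntimeError("boom")

        with pytest.raises(EmbeddingError, match="Q99999"):
            embed("ACD", broken, seq_id="Q99999")

    def test_wrong_shape_rejected(self):
        with pytest.raises(EmbeddingError):
            embed("ACD", lambda s: np.zeros((2, 4)))


class TestDccLayer:
    def test_identity_kernel(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 3))
        out = dcc_layer(x, kernel=[1.0, 0.0, 0.0], dilation=2)
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_causality_perturbation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 2))
        kernel = rng.normal(size=(3, 2, 2))
        base = dcc_layer(x, kernel, dilation=4)
        t = 11
        perturbed = x.copy()
        perturbed[t + 1] += 5.0
        out = dcc_layer(perturbed, kernel, dilation=4)
        np.testing.assert_array_equal(out[:t + 1], base[:t + 1])
        assert not np.array_equal(out, base)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(5, 40))
        c_in, c_out = int(rng.integers(1, 4)), int(rng.integers(1, 4))
        width = int(rng.integers(1, 4))
        dilation = int(rng.integers(1, 6))
        x = rng.normal(size=(length, c_in))
        kernel = rng.normal(size=(width, c_in, c_out))
        bias = rng.normal(size=c_out)
        ours = dcc_layer(x, kernel, dilation, bias=bias)
        np.testing.assert_allclose(ours, naive_dcc(x, kernel, dilation, bias),
                                   atol=1e-10)

    def test_dilation_longer_than_input(self):
        x = np.ones((3, 1))
        out = dcc_layer(x, kernel=[0.0, 1.0], dilation=10)
        np.testing.assert_array_equal(out, np.zeros((3, 1)))

    def test_invalid_dilation(self):
        with pytest.raises(ConfigError):
            DccLayer(taps=[Tensor(np.eye(2))], bias=Tensor(np.zeros(2)),
                     dilation=0)


class TestReceptiveField:
    def test_printed_constants(self):
        dilations = (1, 2, 4, 8)
        assert [receptive_field(q, 3, dilations) for q in (1, 2, 3, 4)] == \
            [3, 7, 15, 31]

    def test_small_case(self):
        assert receptive_field(2, 2, (1, 2)) == 4

    def test_matches_impulse_response_oracle(self):
        for q in (1, 2, 3, 4):
            layers = [DccLayer.from_kernel([1.0, 1.0, 1.0], d, 1)
                      for d in (1, 2, 4, 8)[:q]]

            def stack_fn(x):
                out = Tensor(x)
                for layer in layers:
                    out = layer(out)
                return out.data

            measured = receptive_field_by_impulse(stack_fn, length=40)
            assert measured == receptive_field(q, 3, (1, 2, 4, 8))

    def test_invalid_q(self):
        with pytest.raises(ConfigError):
            receptive_field(0, 3, (1,))


class TestGatedFusion:
    def test_large_bias_limit_is_plain_sum(self):
        rng = np.random.default_rng(2)
        feats = [Tensor(rng.normal(size=(5, 3))) for _ in range(2)]
        w = [Tensor(np.zeros((6, 3))) for _ in range(2)]
        b = [Tensor(np.full(3, 50.0)) for _ in range(2)]  # sigmoid -> 1
        out = gated_multiscale_fusion(feats, w, b)
        np.testing.assert_allclose(out.data, feats[0].data + feats[1].data,
                                   atol=1e-10)

    def test_single_layer_zero_weights_halves(self):
        x = Tensor(np.ones((4, 2)))
        out = gated_multiscale_fusion([x], [Tensor(np.zeros((2, 2)))],
                                      [Tensor(np.zeros(2))])
        np.testing.assert_allclose(out.data, 0.5 * np.ones((4, 2)))

    @pytest.mark.parametrize("seed", range(3))
    def test_gates_in_open_interval(self, seed):
        rng = np.random.default_rng(seed)
        q, c = 3, 4
        feats = [Tensor(rng.normal(size=(6, c))) for _ in range(q)]
        w = [Tensor(rng.normal(size=(q * c, c))) for _ in range(q)]
        b = [Tensor(rng.normal(size=c)) for _ in range(q)]
        stacked = np.concatenate([f.data for f in feats], axis=1)
        for wq, bq in zip(w, b):
            gate = 1 / (1 + np.exp(-(stacked @ wq.data + bq.data)))
            assert np.all(gate > 0) and np.all(gate < 1)
        out = gated_multiscale_fusion(feats, w, b)
        assert np.isfinite(out.data).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DataError):
            gated_multiscale_fusion(
                [Tensor(np.zeros((3, 2))), Tensor(np.zeros((4, 2)))],
                [Tensor(np.zeros((4, 2)))] * 2, [Tensor(np.zeros(2))] * 2)


class TestGlobalLocalFusion:
    def test_gate_one_limit_returns_global(self):
        rng = np.random.default_rng(3)
        f_global = Tensor(rng.normal(size=(5, 3)))
        f_dcc = Tensor(np.zeros((5, 3)))
        out = fuse_global_local(f_global, f_dcc, Tensor(np.zeros((6, 3))),
                                Tensor(np.full(3, 60.0)))
        np.testing.assert_allclose(out.data, f_global.data, atol=1e-10)

    def test_zero_weight_gate_is_half(self):
        f_global = Tensor(np.ones((4, 2)))
        f_dcc = Tensor(np.full((4, 2), 3.0))
        out = fuse_global_local(f_global, f_dcc, Tensor(np.zeros((4, 2))),
                                Tensor(np.zeros(2)))
        np.testing.assert_allclose(out.data, 0.5 * (1.0 + 3.0) * np.ones((4, 2)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        length, k = 6, 4
        f_global = rng.normal(size=(length, k))
        f_dcc = rng.normal(size=(length, k))
        w = rng.normal(size=(2 * k, k))
        b = rng.normal(size=k)
        out = fuse_global_local(Tensor(f_global), Tensor(f_dcc), Tensor(w),
                                Tensor(b))
        gate = 1 / (1 + np.exp(-(np.concatenate([f_global, f_dcc], axis=1) @ w + b)))
        np.testing.assert_allclose(out.data, gate * (f_global + f_dcc), atol=1e-10)

    def test_width_mismatch_rejected(self):
        with pytest.raises(DataError):
            fuse_global_local(Tensor(np.zeros((3, 2))),
                              Tensor(np.zeros((3, 4))),
                              Tensor(np.zeros((6, 2))), Tensor(np.zeros(2)))


class TestPooling:
    def test_single_row(self):
        x = np.array([[1.0, 2.0, 3.0]])
        np.testing.assert_array_equal(pool_to_protein(x).data, x[0])

    def test_constant_rows(self):
        x = np.tile([2.0, -1.0], (7, 1))
        np.testing.assert_allclose(pool_to_protein(x).data, [2.0, -1.0])

    def test_mean_matches_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(9, 5))
        np.testing.assert_allclose(pool_to_protein(x).data, x.mean(axis=0),
                                   atol=1e-12)

    def test_max_mode(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(9, 5))
        np.testing.assert_allclose(pool_to_protein(x, "max").data,
                                   x.max(axis=0), atol=1e-12)

    def test_unknown_mode(self):
        with pytest.raises(ConfigError):
            pool_to_protein(np.ones((2, 2)), "median")


class TestSequenceBlockStack:
    def test_causality_of_full_stack(self):
        rng = np.random.default_rng(6)
        block = SequenceBlock.create(embed_dim=5, channels=4, kernel_width=3,
                                     dilations=(1, 2), rng=rng)
        x = rng.normal(size=(15, 5))
        x_h, _ = block(x)
        t = 7
        perturbed = x.copy()
        perturbed[t + 1:] = 0.0
        x_h2, _ = block(perturbed)
        np.testing.assert_allclose(x_h.data[:t + 1], x_h2.data[:t + 1],
                                   atol=1e-12)

    def test_output_shapes(self):
        rng = np.random.default_rng(7)
        block = SequenceBlock.create(embed_dim=6, channels=3, kernel_width=3,
                                     dilations=(1, 2, 4, 8), rng=rng)
        x_h, pooled = block(rng.normal(size=(20, 6)))
        assert x_h.shape == (20, 3)
        assert pooled.shape == (3,)

    def test_finite_outputs(self):
        rng = np.random.default_rng(8)
        block = SequenceBlock.create(embed_dim=4, channels=4, kernel_width=2,
                                     dilations=(1, 2), rng=rng)
        x_h, pooled = block(rng.normal(size=(30, 4)))
        assert np.isfinite(x_h.data).all()
        assert np.isfinite(pooled.data).all()
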