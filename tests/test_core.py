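import numpy as np
import pytest

from umint.core import (
    Embedding,
    LayerActivations,
    UMINTConfig,
    UMINTParameters,
    build_model,
    compute_loss,
    count_parameters_dense,
    count_parameters_umint,
    decode,
    default_hidden_widths,
    encode,
    load_model,
    parameter_reduction,
    read_embedding_csv,
    save_model,
    train,
    write_embedding_csv,
)
from umint.io_preprocess import ValidationError

from _oracles import finite_difference_gradient_check, loss_scalar_bruteforce


def _cfg(**kw):
    base = dict(hidden_widths=[8, 4], bottleneck_width=3, seed=1)
    base.update(kw)
    return UMINTConfig(**base)


# ---------------------------------------------------------------------------
# closed-form parameter accounting
# ---------------------------------------------------------------------------

class TestParameterCounts:
    def test_modular_count(self):
        assert count_parameters_umint([100, 10], [8, 4]) == 840
        assert count_parameters_umint([7], [3]) == 21
        assert count_parameters_umint([5, 9], [1, 1]) == 14

    def test_dense_count(self):
        assert count_parameters_dense([100, 10], [8, 4]) == 110 * 12
        assert count_parameters_dense([1, 1], [1, 1]) == 4

    def test_single_modality_degenerates_to_dense(self):
        for d, n in [(7, 3), (100, 8), (1, 1)]:
            assert (count_parameters_umint([d], [n])
                    == count_parameters_dense([d], [n]))
        assert parameter_reduction([7], [3]).tp_reduction == 0

    def test_reduction_hand_cases(self):
        pc = parameter_reduction([100, 10], [8, 4])
        assert pc.tp_reduction == 100 * 4 + 10 * 8 == 480
        assert pc.tp_total_reduction == 960
        sym = parameter_reduction([5, 5], [2, 2])
        assert sym.tp_reduction == 20 == sym.tp_ae - sym.tp_umint

    def test_identity_on_random_configs(self, rng):
        for _ in range(100):
            m = int(rng.integers(1, 5))
            d = rng.integers(1, 501, size=m).tolist()
            n = rng.integers(1, 65, size=m).tolist()
            pc = parameter_reduction(d, n)
            assert pc.tp_reduction == pc.tp_ae - pc.tp_umint
            assert pc.tp_total_reduction == 2 * pc.tp_reduction

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            count_parameters_umint([3, 4], [2])


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

class TestBuildModel:
    def test_encoder_weight_entries(self):
        p = build_model([100, 10], _cfg())
        # 100*8 + 10*4 first layer, (8+4)*3 into the bottleneck
        assert p.encoder_weight_entries() == 840
        assert sum(w.size for w in p.W2) == 12 * 3
        assert p.encoder_weight_entries() == count_parameters_umint([100, 10], [8, 4])
        assert p.decoder_weight_entries() == p.encoder_weight_entries()

    def test_single_modality_shapes(self):
        p = build_model([5], UMINTConfig(hidden_widths=[2], bottleneck_width=1))
        assert p.W1[0].shape == (5, 2)
        assert p.W2[0].shape == (2, 1)
        assert p.W3[0].shape == (1, 2)
        assert p.W4[0].shape == (2, 5)

    def test_same_seed_bitwise_identical(self):
        a = build_model([30, 6], _cfg(seed=42))
        b = build_model([30, 6], _cfg(seed=42))
        for x, y in zip(a.arrays(), b.arrays()):
            np.testing.assert_array_equal(x, y)

    def test_bottleneck_wider_than_input_rejected(self):
        with pytest.raises(ValidationError, match="bottleneck"):
            build_model([3, 2], _cfg(bottleneck_width=5))

    def test_dims_widths_mismatch(self):
        with pytest.raises(ValidationError):
            build_model([3, 2, 4], _cfg())

    def test_default_widths_formula(self):
        assert default_hidden_widths([500, 20, 5000]) == [63, 16, 128]


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

def _manual_params(W1, b1, W2, b2, W3, b3, W4, b4):
    as_arr = lambda lst: [np.asarray(a, dtype=float) for a in lst]
    return UMINTParameters(as_arr(W1), as_arr(b1), as_arr(W2),
                           np.asarray(b2, float), as_arr(W3), as_arr(b3),
                           as_arr(W4), as_arr(b4))


class TestEncodeDecode:
    def test_zero_parameters_give_zero_embedding(self, rng):
        p = _manual_params([np.zeros((3, 2))], [np.zeros(2)], [np.zeros((2, 1))],
                           np.zeros(1), [np.zeros((1, 2))], [np.zeros(2)],
                           [np.zeros((2, 3))], [np.zeros(3)])
        emb, _ = encode(p, [rng.normal(size=(4, 3))])
        np.testing.assert_array_equal(emb.values, np.zeros((4, 1)))

    def test_hand_case_relu_then_sum(self):
        # x=[1,-1] through identity weights: h2 = ReLU([1,-1]) = [1,0];
        # ones column into the bottleneck: h3 = [1]
        p = _manual_params([np.eye(2)], [np.zeros(2)], [np.ones((2, 1))],
                           np.zeros(1), [np.zeros((1, 2))], [np.zeros(2)],
                           [np.zeros((2, 2))], [np.zeros(2)])
        emb, acts = encode(p, [np.array([[1.0, -1.0]])])
        np.testing.assert_array_equal(acts.h2[0], [[1.0, 0.0]])
        np.testing.assert_array_equal(emb.values, [[1.0]])

    def test_large_negative_bias_clamps_to_zero(self, rng):
        cfg = _cfg()
        p = build_model([6, 3], cfg)
        for b in p.b1:
            b[:] = -1e6
        emb, acts = encode(p, [rng.normal(size=(5, 6)), rng.normal(size=(5, 3))])
        assert all((h == 0).all() for h in acts.h2)
        # bottleneck sees only its (zero) bias
        np.testing.assert_array_equal(emb.values, np.zeros((5, cfg.bottleneck_width)))

    def test_embedding_nonnegative_for_random_params(self, rng):
        for seed in range(5):
            p = build_model([10, 4], _cfg(seed=seed))
            x = [rng.normal(size=(20, 10)) * 10, rng.normal(size=(20, 4)) * 10]
            emb, acts = encode(p, x)
            assert emb.values.min() >= 0
            assert min(h.min() for h in acts.h2) >= 0

    def test_decode_hand_case(self):
        # k=1 embedding [2]; W3=[[1,-1]]: h4 = ReLU([2,-2]) = [2,0];
        # W4 rows of ones: xhat = [2, 2] masked by the dead unit -> [2, 2]*[1,0]
        p = _manual_params([np.zeros((2, 2))], [np.zeros(2)], [np.zeros((2, 1))],
                           np.zeros(1), [np.array([[1.0, -1.0]])], [np.zeros(2)],
                           [np.array([[1.0, 1.0], [1.0, 1.0]])], [np.zeros(2)])
        recons, h4 = decode(p, Embedding(np.array([[2.0]]), ["c0"]))
        np.testing.assert_array_equal(h4[0], [[2.0, 0.0]])
        np.testing.assert_array_equal(recons[0], [[2.0, 2.0]])

    def test_roundtrip_shapes(self, rng):
        p = build_model([9, 5], _cfg())
        x = [rng.normal(size=(7, 9)), rng.normal(size=(7, 5))]
        emb, _ = encode(p, x)
        recons, _ = decode(p, emb)
        assert [r.shape for r in recons] == [(7, 9), (7, 5)]

    def test_dimension_mismatch_names_modality(self, rng):
        p = build_model([9, 5], _cfg())
        with pytest.raises(ValidationError, match="modality 1"):
            encode(p, [rng.normal(size=(7, 9)), rng.normal(size=(7, 6))])


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

class TestComputeLoss:
    def test_perfect_reconstruction_no_penalties(self, rng):
        p = build_model([4, 2], _cfg(alpha=0.0, beta=0.0))
        x = [rng.random((3, 4)), rng.random((3, 2))]
        acts = LayerActivations([np.zeros((3, 8)), np.zeros((3, 4))],
                                np.zeros((3, 3)),
                                [np.zeros((3, 8)), np.zeros((3, 4))])
        loss = compute_loss(p, x, acts, [x[0].copy(), x[1].copy()],
                            _cfg(alpha=0.0, beta=0.0))
        assert loss.total == 0.0

    def test_single_modality_hand_value(self):
        # n=1, residual [2, 0], lambda=0.5 -> 0.5 * 4 / 1 = 2
        p = build_model([2], UMINTConfig(hidden_widths=[2], bottleneck_width=1,
                                         lambdas=[0.5], alpha=0.0, beta=0.0))
        x = [np.array([[2.0, 0.0]])]
        acts = LayerActivations([np.zeros((1, 2))], np.zeros((1, 1)),
                                [np.zeros((1, 2))])
        loss = compute_loss(p, x, acts, [np.zeros((1, 2))],
                            UMINTConfig(hidden_widths=[2], bottleneck_width=1,
                                        lambdas=[0.5], alpha=0.0, beta=0.0))
        assert loss.reconstruction_terms == [2.0]
        assert loss.total == 2.0

    def test_single_active_unit_activity_penalty(self):
        cfg = UMINTConfig(hidden_widths=[2], bottleneck_width=1, lambdas=[0.0],
                          alpha=0.0001, beta=0.0)
        p = build_model([2], cfg)
        acts = LayerActivations([np.zeros((1, 2))], np.array([[1.0]]),
                                [np.zeros((1, 2))])
        loss = compute_loss(p, [np.zeros((1, 2))], acts, [np.zeros((1, 2))], cfg)
        assert loss.activity_penalty == pytest.approx(0.0001)

    def test_total_is_sum_of_parts(self, rng):
        cfg = _cfg(alpha=1e-3, beta=1e-2)
        p = build_model([5, 3], cfg)
        x = [rng.normal(size=(6, 5)), rng.normal(size=(6, 3))]
        emb, acts = encode(p, x)
        recons, h4 = decode(p, emb)
        acts = LayerActivations(acts.h2, acts.h3, h4)
        loss = compute_loss(p, x, acts, recons, cfg)
        parts = sum(loss.reconstruction_terms) + loss.activity_penalty + loss.weight_penalty
        assert loss.total == pytest.approx(parts, rel=1e-12)

    def test_matches_entrywise_scalar_rederivation(self, rng):
        cfg = UMINTConfig(hidden_widths=[3, 2], bottleneck_width=2,
                          lambdas=[0.7, 1.3], alpha=2e-3, beta=5e-3)
        p = build_model([4, 3], cfg)
        x = [rng.normal(size=(5, 4)), rng.normal(size=(5, 3))]
        emb, acts = encode(p, x)
        recons, h4 = decode(p, emb)
        acts = LayerActivations(acts.h2, acts.h3, h4)
        loss = compute_loss(p, x, acts, recons, cfg)
        oracle = loss_scalar_bruteforce(p, x, acts, recons, cfg.resolve([4, 3]))
        assert loss.total == pytest.approx(oracle, rel=1e-9)

    def test_negative_coefficients_rejected(self):
        with pytest.raises(ValidationError):
            _cfg(alpha=-1.0).resolve([5, 3])
        with pytest.raises(ValidationError):
            UMINTConfig(hidden_widths=[2], bottleneck_width=1,
                        lambdas=[-0.5]).resolve([4])

    def test_auto_lambda_balances_feature_duplication(self, rng):
        """Duplicating every feature of a modality (and its reconstruction)
        leaves that modality's reconstruction term unchanged under lambda=1/d."""
        cfg = UMINTConfig(hidden_widths=[3, 2], bottleneck_width=2, lambdas="auto")
        p = build_model([4, 3], cfg)
        x = [rng.normal(size=(6, 4)), rng.normal(size=(6, 3))]
        emb, acts = encode(p, x)
        recons, h4 = decode(p, emb)
        acts = LayerActivations(acts.h2, acts.h3, h4)
        base = compute_loss(p, x, acts, recons, cfg)

        x_dup = [np.hstack([x[0], x[0]]), x[1]]
        recons_dup = [np.hstack([recons[0], recons[0]]), recons[1]]
        dup = compute_loss(p, x_dup, acts, recons_dup, cfg)
        assert dup.reconstruction_terms[0] == pytest.approx(
            base.reconstruction_terms[0], rel=1e-12)


# ---------------------------------------------------------------------------
# gradients & training
# ---------------------------------------------------------------------------

class TestGradients:
    def test_finite_differences_every_layer(self, rng):
        """Central finite differences vs the analytic gradient on a 10-cell,
        2-modality fixture, sampling entries from every parameter array
        (samples landing on a ReLU kink are rejected — the objective is not
        differentiable there)."""
        rcfg = UMINTConfig(hidden_widths=[4, 3], bottleneck_width=3,
                           lambdas=[0.5, 2.0], alpha=1e-4, beta=1e-3,
                           seed=5).resolve([7, 4])
        p = build_model([7, 4], rcfg)
        mats = [rng.normal(size=(10, 7)), rng.normal(size=(10, 4))]
        worst, checked = finite_difference_gradient_check(
            p, mats, rcfg, rng, samples_per_array=3)
        assert checked >= 40
        assert worst < 1e-4


class TestTrain:
    def test_loss_decreases_on_structured_data(self, small_processed):
        cfg = UMINTConfig(hidden_widths=[16, 8], bottleneck_width=8,
                          epochs=8, seed=2)
        _, history = train(small_processed, cfg)
        assert history[-1].total < history[0].total

    def test_zero_data_converges_to_zero(self):
        cfg = UMINTConfig(hidden_widths=[4], bottleneck_width=2,
                          alpha=0.0, beta=0.0, epochs=40, seed=3)
        x = [np.zeros((32, 6))]
        _, history = train(x, cfg)
        assert history[-1].total < 1e-4

    def test_same_seed_same_trace(self, small_processed):
        cfg = UMINTConfig(hidden_widths=[16, 8], bottleneck_width=8,
                          epochs=3, seed=9)
        _, h1 = train(small_processed, cfg)
        _, h2 = train(small_processed, cfg)
        for a, b in zip(h1, h2):
            assert a.total == pytest.approx(b.total, abs=1e-6)

    def test_n_smaller_than_batch_is_one_batch(self, rng):
        cfg = UMINTConfig(hidden_widths=[3], bottleneck_width=2, epochs=2,
                          batch_size=64, seed=0)
        _, history = train([rng.normal(size=(10, 5))], cfg)
        assert len(history) == 2


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

class TestPersistence:
    def test_model_archive_roundtrip(self, tmp_path, rng):
        cfg = _cfg(alpha=3e-4)
        p = build_model([12, 5], cfg)
        path = tmp_path / "model.npz"
        save_model(p, cfg, path)
        q, cfg2 = load_model(path)
        for a, b in zip(p.arrays(), q.arrays()):
            np.testing.assert_array_equal(a, b)
        assert cfg2.alpha == 3e-4
        x = [rng.normal(size=(4, 12)), rng.normal(size=(4, 5))]
        np.testing.assert_array_equal(encode(p, x)[0].values,
                                      encode(q, x)[0].values)

    def test_embedding_csv_roundtrip(self, tmp_path, rng):
        emb = Embedding(rng.random((5, 3)), [f"c{i}" for i in range(5)])
        path = tmp_path / "emb.csv"
        write_embedding_csv(emb, path)
        header = path.read_text().splitlines()[0]
        assert header == "cell_id,UMINT_1,UMINT_2,UMINT_3"
        back = read_embedding_csv(path)
        assert back.cell_ids == emb.cell_ids
        np.testing.assert_allclose(back.values, emb.values, atol=1e-12)
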