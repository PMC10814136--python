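"""The seven regressors: closed-form blocks, architecture contracts, training."""

import numpy as np
import pytest

import spectrareg as sr
from spectrareg.exceptions import DivergedTrainingError, ParameterError
from spectrareg.models import (
    CnnLstmSpec,
    CnnSpec,
    LstmSpec,
    TrainConfig,
    TransformerSpec,
    build_model,
    fit_plsr,
    fit_svr,
    n_parameters,
    train_model,
)


class TestPositionalEncoding:
    def test_row_zero_alternates_zero_one(self):
        pe = sr.positional_encoding(5, 8)
        np.testing.assert_allclose(pe[0, 0::2], 0.0)
        np.testing.assert_allclose(pe[0, 1::2], 1.0)

    def test_first_position_first_column_is_sin_one(self):
        pe = sr.positional_encoding(4, 6)
        assert pe[1, 0] == pytest.approx(np.sin(1.0), abs=1e-12)

    def test_matches_two_loop_oracle(self):
        seq_len, d_model = 13, 10
        pe = sr.positional_encoding(seq_len, d_model)
        expected = np.empty((seq_len, d_model))
        for pos in range(seq_len):
            for i in range(0, d_model, 2):
                angle = pos / 10000 ** (i / d_model)
                expected[pos, i] = np.sin(angle)
                expected[pos, i + 1] = np.cos(angle)
        np.testing.assert_allclose(pe, expected, atol=1e-12)
        assert np.all(np.abs(pe) <= 1.0)

    def test_odd_dimension_rejected(self):
        with pytest.raises(ParameterError):
            sr.positional_encoding(5, 7)


class TestScaledAttention:
    def test_single_key_returns_its_value_for_every_query(self, rng):
        q = rng.normal(size=(5, 3))
        k = rng.normal(size=(1, 3))
        v = rng.normal(size=(1, 4))
        out = sr.scaled_attention(q, k, v)
        np.testing.assert_allclose(out, np.tile(v, (5, 1)), atol=1e-12)

    def test_matches_brute_force_loop_oracle(self, rng):
        q, k, v = rng.normal(size=(4, 8)), rng.normal(size=(6, 8)), rng.normal(size=(6, 5))
        out = sr.scaled_attention(q, k, v)
        expected = np.zeros((4, 5))
        for i in range(4):
            logits = np.array([q[i] @ k[j] / np.sqrt(8) for j in range(6)])
            w = np.exp(logits)
            w = w / w.sum()
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            for j in range(6):
                expected[i] += w[j] * v[j]
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_joint_key_value_permutation_leaves_output_unchanged(self, rng):
        q, k, v = rng.normal(size=(3, 4)), rng.normal(size=(5, 4)), rng.normal(size=(5, 2))
        perm = rng.permutation(5)
        np.testing.assert_allclose(sr.scaled_attention(q, k, v),
                                   sr.scaled_attention(q, k[perm], v[perm]), atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ParameterError):
            sr.scaled_attention(rng.normal(size=(3, 4)), rng.normal(size=(5, 3)),
                                rng.normal(size=(5, 2)))


SMALL_SPECS = {
    "cnn": CnnSpec(conv_channels=(4, 8), fc_hidden=8),
    "lstm": LstmSpec(input_dim=16, hidden_dim=12),
    "cnn_lstm": CnnLstmSpec(conv_channels=(4, 6, 8), lstm_hidden=6),
    "transformer": TransformerSpec(d_model=8, n_layers=2, n_heads=2, ff_hidden=16,
                                   front_end="none"),
    "cnn_transformer": TransformerSpec(d_model=8, n_layers=2, n_heads=2, ff_hidden=16,
                                       conv_channels=(4, 8)),
}


class TestArchitectures:
    @pytest.mark.parametrize("kind", list(SMALL_SPECS))
    def test_output_shape_is_batch_by_one(self, kind, rng):
        model = build_model(kind, 20, spec=SMALL_SPECS[kind], seed=0)
        out = model(rng.normal(size=(10, 20)).astype(np.float32))
        assert out.shape == (10, 1)
        assert np.all(np.isfinite(out.data))

    @pytest.mark.parametrize("kind", list(SMALL_SPECS))
    def test_eval_mode_forward_is_deterministic(self, kind, rng):
        model = build_model(kind, 20, spec=SMALL_SPECS[kind], seed=0)
        x = rng.normal(size=(4, 20)).astype(np.float32)
        model.eval()
        np.testing.assert_array_equal(model(x).data, model(x).data)

    def test_same_seed_gives_identical_initialisation(self):
        a = build_model("cnn_transformer", 20, spec=SMALL_SPECS["cnn_transformer"], seed=5)
        b = build_model("cnn_transformer", 20, spec=SMALL_SPECS["cnn_transformer"], seed=5)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_cnn_transformer_parameter_count_closed_form(self):
        # hand-derived once from the layer dimensions and frozen:
        # bias-free conv(1->128,k3)+conv(128->256,k3) + 6 encoder layers
        # (4x256x256 proj, two LayerNorms, 256->1024->256 FF) + head
        model = build_model("cnn_transformer", 209, seed=0)
        conv = 128 * 3 + 256 * 128 * 3
        per_layer = 4 * (256 * 256 + 256) + 2 * (2 * 256) \
            + (256 * 1024 + 1024) + (1024 * 256 + 256)
        head = 256 + 1
        assert n_parameters(model) == conv + 6 * per_layer + head == 4_837_505

    def test_spec_invariant_violations_rejected(self):
        with pytest.raises(ParameterError):
            build_model("cnn_transformer", 20,
                        spec=TransformerSpec(d_model=10, n_heads=4, conv_channels=(4, 10)))
        with pytest.raises(ParameterError):
            build_model("unknown_kind", 20)


class TestTraining:
    def _linear_data(self, n=80, bands=24, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, bands))
        w = np.zeros(bands)
        w[5] = 2.0
        y = x @ w + noise * rng.normal(size=n)
        return x, y

    def test_constant_target_is_learned(self):
        x, _ = self._linear_data(n=40, bands=12)
        y = np.full(40, 7.0)
        model = build_model("cnn", 12, spec=SMALL_SPECS["cnn"], seed=0)
        cfg = TrainConfig(lr=0.002, max_epochs=60, patience=60, seed=0)
        trained = train_model(model, x[:30], y[:30], x[30:], y[30:], cfg)
        rmse_cal = np.sqrt(np.mean((trained.predict(x[:30]) - y[:30]) ** 2))
        assert rmse_cal < 0.01 * (1 + 7.0)

    def test_best_epoch_train_loss_not_worse_than_first(self):
        x, y = self._linear_data()
        model = build_model("cnn", 24, spec=SMALL_SPECS["cnn"], seed=1)
        cfg = TrainConfig(lr=0.001, max_epochs=30, patience=30, seed=1)
        trained = train_model(model, x[:60], y[:60], x[60:], y[60:], cfg)
        history = trained.history
        assert history[trained.best_epoch - 1]["train_loss"] <= history[0]["train_loss"]

    def test_cnn_learns_linear_single_band_signal(self):
        x, y = self._linear_data(n=100, bands=24, noise=0.05, seed=3)
        model = build_model("cnn", 24, spec=SMALL_SPECS["cnn"], seed=3)
        cfg = TrainConfig(lr=0.0005, max_epochs=200, patience=200, seed=3)
        trained = train_model(model, x[:75], y[:75], x[75:], y[75:], cfg)
        pred = trained.predict(x[75:])
        assert sr.r_squared(y[75:], pred) >= 0.9

    def test_training_is_reproducible_for_fixed_seed(self):
        x, y = self._linear_data(n=30, bands=10)
        out = []
        for _ in range(2):
            model = build_model("lstm", 10, spec=SMALL_SPECS["lstm"], seed=4)
            cfg = TrainConfig(lr=0.001, max_epochs=5, patience=5, seed=4)
            trained = train_model(model, x[:20], y[:20], x[20:], y[20:], cfg)
            out.append(trained.predict(x[20:]))
        np.testing.assert_array_equal(out[0], out[1])

    def test_divergence_is_reported_with_epoch(self):
        x, y = self._linear_data(n=20, bands=8)
        model = build_model("cnn", 8, spec=CnnSpec(conv_channels=(4, 8), fc_hidden=8), seed=0)
        model.parameters()[0].data[:] = 1e30  # force overflow
        cfg = TrainConfig(lr=1e3, max_epochs=3, patience=3, seed=0)
        with pytest.raises(DivergedTrainingError):
            train_model(model, x[:15], y[:15], x[15:], y[15:], cfg)


class TestSerialization:
    @pytest.mark.parametrize("kind", ["cnn", "cnn_transformer"])
    def test_save_load_round_trip_preserves_predictions(self, kind, tmp_path, rng):
        from spectrareg.models import load_model, save_model

        x = rng.normal(size=(30, 20))
        y = x[:, 3] * 2 + 5
        model = build_model(kind, 20, spec=SMALL_SPECS[kind], seed=2)
        cfg = TrainConfig(lr=0.001, max_epochs=3, patience=3, seed=2)
        trained = train_model(model, x[:20], y[:20], x[20:], y[20:], cfg, kind=kind)
        path = tmp_path / "model.npz"
        save_model(trained, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(loaded.predict(x), trained.predict(x))
        assert loaded.best_epoch == trained.best_epoch
        assert len(loaded.history) == len(trained.history)

    def test_classical_models_are_rejected(self, rng, tmp_path):
        from spectrareg.models import save_model

        x = rng.normal(size=(30, 8))
        trained = fit_plsr(x, x[:, 0])
        with pytest.raises(ParameterError):
            save_model(trained, tmp_path / "m.npz")


class TestClassicalModels:
    def test_plsr_recovers_noiseless_low_rank_signal(self, rng):
        n, b = 60, 30
        x = rng.normal(size=(n, b))
        w = np.zeros(b)
        w[:5] = rng.normal(size=5)
        y = x @ w
        trained = fit_plsr(x, y)
        assert 1 <= trained.extra["n_components"] <= 21
        assert sr.r_squared(y, trained.predict(x)) >= 0.999

    def test_plsr_matches_hand_coded_nipals_oracle(self, rng):
        x = rng.random((6, 4))
        y = rng.random(6)
        from sklearn.cross_decomposition import PLSRegression

        k = 2
        model = PLSRegression(n_components=k, scale=False).fit(x, y)

        # independent NIPALS (PLS1) with deflation
        xc = x - x.mean(0)
        yc = y - y.mean()
        xd, yd = xc.copy(), yc.copy()
        ws, ps, qs = [], [], []
        for _ in range(k):
            wv = xd.T @ yd
            wv = wv / np.linalg.norm(wv)
            tv = xd @ wv
            pv = xd.T @ tv / (tv @ tv)
            qv = (yd @ tv) / (tv @ tv)
            xd = xd - np.outer(tv, pv)
            yd = yd - qv * tv
            ws.append(wv)
            ps.append(pv)
            qs.append(qv)
        w_mat, p_mat, q_vec = np.array(ws).T, np.array(ps).T, np.array(qs)
        beta = w_mat @ np.linalg.solve(p_mat.T @ w_mat, q_vec)
        oracle_pred = xc @ beta + y.mean()
        np.testing.assert_allclose(model.predict(x).ravel(), oracle_pred, atol=1e-8)

    def test_svr_selects_from_declared_grids(self, rng):
        x = rng.normal(size=(50, 10))
        y = x[:, 0] * 2 + rng.normal(scale=0.1, size=50)
        spec = sr.SvrSpec(gamma_grid=tuple(np.logspace(-4, 5, 4)), cv_folds=3)
        trained = fit_svr(x, y, spec)
        params = trained.extra["best_params"]
        assert params["C"] in spec.c_grid
        assert params["kernel"] in ("linear", "poly", "rbf")
        assert sr.r_squared(y, trained.predict(x)) > 0.8

    def test_predict_rejects_wrong_width(self, rng):
        x = rng.normal(size=(30, 8))
        y = x[:, 0]
        trained = fit_plsr(x, y)
        with pytest.raises(ParameterError):
            trained.predict(rng.normal(size=(5, 9)))
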