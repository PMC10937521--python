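"""LASSO bank and MLP: losses, gradient training oracles, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fedgen.models import (
    AncestryMLP,
    LassoBankModel,
    LassoBankSpec,
    MLPSpec,
    accuracy,
    count_params,
    cross_entropy,
    lambda_max,
    lasso_loss,
    make_lambda_grid,
    mlp_forward,
    r2_score,
    selu,
    soft_threshold,
)


def standardized_design(rng, n=200, p=5):
    X = rng.normal(size=(n, p))
    X = (X - X.mean(0)) / X.std(0)
    beta = rng.normal(size=p) * np.array([1, 1, 1, 0, 1])[:p]
    y = X @ beta + rng.normal(0, 0.5, n) + 0.7
    return X, y


def centered_orthonormal_design(rng, n=200, p=5):
    Z = rng.normal(size=(n, p))
    q, _ = np.linalg.qr(Z - Z.mean(0))
    X = q * np.sqrt(n)  # X'X = n I and columns centered
    y = X @ np.array([1.0, -2.0, 0.5, 0.0, 3.0])[:p] + rng.normal(0, 0.5, n)
    return X, y


def train_full_batch(spec, X, y, lr, epochs, seed=1):
    params = spec.init_params()
    rng = np.random.default_rng(seed)
    for _ in range(epochs):
        params = spec.train_epoch(params, (X, y), lr, None, rng)
    return params


class TestModelParams:
    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_flatten_unflatten_round_trip(self, seed):
        spec = MLPSpec(4, (6, 5), 3)
        params = spec.init_params(seed)
        rebuilt = params.unflatten(params.flatten())
        for k in params.tensors:
            assert np.array_equal(rebuilt.tensors[k], params.tensors[k])

    def test_round_trip_for_bank(self):
        spec = LassoBankSpec(7, np.array([1.0, 0.1]))
        params = spec.init_params()
        params.tensors["weights"] += 3.0
        rebuilt = params.unflatten(params.flatten())
        assert np.array_equal(rebuilt.tensors["weights"], params.tensors["weights"])

    def test_wrong_length_rejected(self):
        spec = LassoBankSpec(3, np.array([1.0]))
        params = spec.init_params()
        with pytest.raises(ValueError):
            params.unflatten(np.zeros(99))


class TestLassoLoss:
    def test_zero_model_on_centered_response_gives_variance(self, rng):
        X, y = standardized_design(rng)
        y = y - y.mean()
        L = 4
        losses = lasso_loss(np.zeros((L, 5)), np.zeros(L), np.ones(L), X, y)
        assert np.allclose(losses, y.var())

    def test_lambda_zero_is_plain_mse(self, rng):
        X, y = standardized_design(rng)
        W = rng.normal(size=(1, 5))
        b = np.array([0.3])
        loss = lasso_loss(W, b, np.array([0.0]), X, y)[0]
        mse = np.mean((y - X @ W[0] - 0.3) ** 2)
        assert loss == pytest.approx(mse)

    def test_hand_two_feature_example(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array([1.0, -1.0])
        W = np.array([[0.5, -0.5]])
        b = np.array([0.0])
        # residuals (0.5, -0.5) -> mse 0.25; penalty 2 * 0.5 * |.| terms
        loss = lasso_loss(W, b, np.array([2.0]), X, y)[0]
        assert loss == pytest.approx(0.25 + 2.0 * 1.0)


class TestLassoTraining:
    def test_lambda_zero_converges_to_ols(self, rng):
        X, y = standardized_design(rng)
        spec = LassoBankSpec(5, np.array([0.0]))
        params = train_full_batch(spec, X, y, lr=0.05, epochs=4000)
        A = np.column_stack([np.ones(len(y)), X])
        ols = np.linalg.lstsq(A, y, rcond=None)[0]
        assert np.abs(params.tensors["weights"][0] - ols[1:]).max() <= 1e-6
        assert abs(params.tensors["intercepts"][0] - ols[0]) <= 1e-6

    def test_lambda_max_gives_null_model(self, rng):
        X, y = standardized_design(rng)
        lam = lambda_max(X, y)
        spec = LassoBankSpec(5, np.array([lam * 1.001]))
        params = train_full_batch(spec, X, y, lr=0.05, epochs=2000)
        assert np.all(params.tensors["weights"] == 0.0)

    def test_orthonormal_design_soft_threshold_solution(self, rng):
        X, y = centered_orthonormal_design(rng)
        lam = 0.8
        spec = LassoBankSpec(5, np.array([lam]))
        params = train_full_batch(spec, X, y, lr=0.02, epochs=3000)
        expected = soft_threshold(X.T @ y / len(y), lam / 2.0)
        assert np.abs(params.tensors["weights"][0] - expected).max() <= 1e-6

    def test_matches_sklearn_coordinate_descent(self, rng):
        # independent solver on a general design; alpha = lambda / 2 maps
        # sklearn's (1/2n) RSS convention onto the mean-squared-error loss
        from sklearn.linear_model import Lasso

        X, y = standardized_design(rng)
        lam = 0.3
        spec = LassoBankSpec(5, np.array([lam]))
        params = train_full_batch(spec, X, y, lr=0.02, epochs=6000)
        sk = Lasso(alpha=lam / 2.0).fit(X, y)
        assert np.abs(params.tensors["weights"][0] - sk.coef_).max() <= 1e-5
        assert abs(params.tensors["intercepts"][0] - sk.intercept_) <= 1e-5

    def test_bank_bit_identical_to_separate_models(self, rng):
        X, y = standardized_design(rng, n=120)
        lams = make_lambda_grid(lambda_max(X, y), 8)
        bank = LassoBankSpec(5, lams)
        pb = bank.init_params()
        r = np.random.default_rng(5)
        for _ in range(4):
            pb = bank.train_epoch(pb, (X, y), 0.01, 16, r)
        for i, lam in enumerate(lams):
            single = LassoBankSpec(5, np.array([lam]))
            ps = single.init_params()
            rs = np.random.default_rng(5)
            for _ in range(4):
                ps = single.train_epoch(ps, (X, y), 0.01, 16, rs)
            assert np.array_equal(ps.tensors["weights"][0], pb.tensors["weights"][i])
            assert ps.tensors["intercepts"][0] == pb.tensors["intercepts"][i]

    def test_sparsity_nonincreasing_in_lambda(self, rng):
        X, y = standardized_design(rng, n=300, p=5)
        lams = make_lambda_grid(lambda_max(X, y), 12)
        spec = LassoBankSpec(5, lams)
        params = train_full_batch(spec, X, y, lr=0.02, epochs=3000)
        nnz = (np.abs(params.tensors["weights"]) > 1e-10).sum(axis=1)
        assert np.all(np.diff(nnz) >= 0)  # grid decreasing -> nnz nondecreasing

    def test_non_finite_loss_aborts(self, rng):
        X, y = standardized_design(rng)
        spec = LassoBankSpec(5, np.array([0.0]))
        with pytest.raises(FloatingPointError):
            train_full_batch(spec, X, 1e155 * y, lr=1e150, epochs=5)

    def test_model_wrapper_selects_lambda_by_validation(self, rng):
        X, y = standardized_design(rng, n=400)
        model = LassoBankModel(X[:300], y[:300], n_lambda=8)
        res = model.fit(epochs=50, lr=0.02, decay=1.0, batch_size=32,
                        X_val=X[300:], y_val=y[300:])
        assert 0 <= res.selected < 8
        assert res.val_mse[res.selected] == res.val_mse.min()
        assert "selected lambda" in res.summary()


class TestMLP:
    def test_published_architecture_parameter_count(self):
        # 20*800+800 + 800*200+200 + 200*26+26
        assert count_params(20, (800, 200), 26) == 182_226
        spec = MLPSpec(20, (800, 200), 26)
        assert spec.init_params(0).n_values == 182_226

    def test_selu_at_zero_is_zero(self):
        assert selu(np.array([0.0]))[0] == 0.0

    def test_zero_params_give_uniform_scores_and_ln26_loss(self):
        spec = MLPSpec(20, (800, 200), 26)
        params = spec.init_params(0)
        for k in params.tensors:
            params.tensors[k][:] = 0.0
        scores = mlp_forward(params, np.zeros((3, 20)))
        assert np.all(scores == 0.0)
        loss = cross_entropy(scores, np.array([0, 13, 25]))
        assert loss == pytest.approx(np.log(26), abs=1e-6)

    def test_cross_entropy_saturates_to_zero(self):
        scores = np.full((4, 26), -100.0)
        labels = np.array([1, 5, 7, 19])
        scores[np.arange(4), labels] = 100.0
        assert cross_entropy(scores, labels) < 1e-6

    def test_cross_entropy_hand_two_class(self):
        scores = np.array([[2.0, 0.0]])
        expected = -np.log(np.exp(2.0) / (np.exp(2.0) + 1.0))
        assert cross_entropy(scores, np.array([0])) == pytest.approx(expected)

    def test_gradient_matches_finite_differences(self):
        spec = MLPSpec(3, (4, 3), 2, dtype=np.float64)
        params = spec.init_params(0)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 3))
        y = np.array([0, 1, 1, 0, 1])
        loss, grads = spec._loss_and_grad(params, X, y)
        eps = 1e-6
        for name in ("W0", "b1", "W2"):
            t = params.tensors[name]
            idx = tuple(0 for _ in t.shape)
            t[idx] += eps
            up, _ = spec._loss_and_grad(params, X, y)
            t[idx] -= 2 * eps
            down, _ = spec._loss_and_grad(params, X, y)
            t[idx] += eps
            numeric = (up - down) / (2 * eps)
            assert grads[name][idx] == pytest.approx(numeric, abs=1e-5)

    def test_overfits_small_random_sample(self):
        # optimization sanity: 64 random points memorized within 2000 epochs
        rng = np.random.default_rng(3)
        X = rng.normal(size=(64, 20))
        y = rng.integers(0, 26, 64)
        res = AncestryMLP(X, y).fit(epochs=2000, lr=0.1, decay=1.0, batch_size=64, seed=0)
        assert res.score(X, y) == 1.0

    def test_input_width_mismatch_rejected(self):
        spec = MLPSpec(20, (8, 4), 3)
        with pytest.raises(ValueError):
            mlp_forward(spec.init_params(0), np.zeros((2, 7)))


class TestMetrics:
    def test_r2_perfect_prediction(self, rng):
        y = rng.normal(size=50)
        assert r2_score(y, y) == 1.0

    def test_r2_mean_predictor_zero(self, rng):
        y = rng.normal(size=50)
        assert r2_score(y, np.full(50, y.mean())) == pytest.approx(0.0)

    def test_r2_worse_than_mean_negative(self, rng):
        y = rng.normal(size=50)
        assert r2_score(y, -5 * y) < 0

    def test_r2_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r2_score(np.ones(10), np.zeros(10))

    @pytest.mark.parametrize(
        "true,pred,expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 1, 1], [2, 2, 2], 0.0),
            ([0, 1, 2, 3], [0, 1, 2, 9], 0.75),
        ],
    )
    def test_accuracy(self, true, pred, expected):
        assert accuracy(np.array(true), np.array(pred)) == expected


class TestCheckpoints:
    def test_round_trip_with_manifest(self, tmp_path):
        from fedgen.models import load_checkpoint, save_checkpoint

        spec = MLPSpec(4, (6, 5), 3)
        params = spec.init_params(7)
        save_checkpoint(params, tmp_path / "ckpt", metadata={"note": "x"})
        assert (tmp_path / "ckpt.json").exists()
        back, meta = load_checkpoint(tmp_path / "ckpt")
        assert back.kind == params.kind
        assert meta == {"note": "x"}
        for k in params.tensors:
            assert np.array_equal(back.tensors[k], params.tensors[k])

    def test_bank_checkpoint_keeps_lambda_grid(self, tmp_path):
        from fedgen.models import load_checkpoint, save_checkpoint

        lams = make_lambda_grid(1.0, 4)
        spec = LassoBankSpec(3, lams)
        params = spec.init_params()
        save_checkpoint(params, tmp_path / "bank", metadata={"lambdas": lams.tolist()})
        _, meta = load_checkpoint(tmp_path / "bank")
        assert np.allclose(meta["lambdas"], lams)

    def test_manifest_mismatch_rejected(self, tmp_path):
        import json

        from fedgen.models import load_checkpoint, save_checkpoint

        spec = LassoBankSpec(3, np.array([0.5]))
        save_checkpoint(spec.init_params(), tmp_path / "c")
        manifest = json.loads((tmp_path / "c.json").read_text())
        manifest["tensors"]["weights"]["shape"] = [9, 9]
        (tmp_path / "c.json").write_text(json.dumps(manifest))
        with pytest.raises(ValueError):
            load_checkpoint(tmp_path / "c")
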