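"""FedAvg engine: aggregation, degenerate equivalences, selection rules and
communication accounting."""

import numpy as np
import pytest

from fedgen.fedtrain import (
    FedSchedule,
    RoundLog,
    fedavg_aggregate,
    federated_lambda_select,
    model_comm_cost,
    run_fedavg,
    train_local,
)
from fedgen.models import LassoBankSpec, MLPSpec, ModelParams, make_lambda_grid


def scalar_params(value, kind="lasso_bank"):
    return ModelParams(kind, {"w": np.array([float(value)])})


def lasso_problem(rng, n=60, p=8):
    X = rng.normal(size=(n, p))
    X = (X - X.mean(0)) / X.std(0)
    y = X @ rng.normal(size=p) + rng.normal(0, 0.3, n)
    return X, y


class TestAggregate:
    def test_single_client_unchanged(self):
        p = scalar_params(3.7)
        out = fedavg_aggregate([p], np.array([5]))
        assert out.tensors["w"][0] == 3.7

    def test_equal_clients_midpoint(self):
        out = fedavg_aggregate([scalar_params(0.0), scalar_params(2.0)], np.array([10, 10]))
        assert out.tensors["w"][0] == 1.0

    def test_weighted_average_by_hand(self):
        # n = (1, 2, 5), params (8, 4, 0) -> (8 + 8 + 0)/8 = 2
        out = fedavg_aggregate(
            [scalar_params(8), scalar_params(4), scalar_params(0)],
            np.array([1, 2, 5]),
        )
        assert out.tensors["w"][0] == pytest.approx(2.0)

    def test_identical_params_fixed_point(self, rng):
        spec = MLPSpec(4, (5, 4), 3, dtype=np.float64)
        p = spec.init_params(0)
        out = fedavg_aggregate([p.copy(), p.copy(), p.copy()], np.array([3, 4, 5]))
        for k in p.tensors:
            assert np.abs(out.tensors[k] - p.tensors[k]).max() <= 1e-12

    def test_mismatched_shapes_rejected(self):
        a = ModelParams("m", {"w": np.zeros(3)})
        b = ModelParams("m", {"w": np.zeros(4)})
        with pytest.raises(ValueError):
            fedavg_aggregate([a, b], np.array([1, 1]))


class TestClientUpdateDegenerate:
    def test_zero_lr_is_identity(self, rng):
        X, y = lasso_problem(rng)
        spec = LassoBankSpec(8, np.array([0.1]))
        sched = FedSchedule(rounds=3, epochs_per_round=2, lr=0.0, batch_size=16)
        res = run_fedavg(spec, [((X, y), (X, y))], sched, seed=0)
        assert np.all(res.final_params.tensors["weights"] == 0.0)

    def test_single_client_federation_equals_local_training(self, rng):
        X, y = lasso_problem(rng, n=80)
        Xv, yv = lasso_problem(rng, n=20)
        spec = LassoBankSpec(8, make_lambda_grid(0.5, 4))
        sched = FedSchedule(rounds=6, epochs_per_round=3, lr=0.01, decay=0.99, batch_size=16)
        fed = run_fedavg(spec, [((X, y), (Xv, yv))], sched, seed=11)
        loc = train_local(spec, (X, y), (Xv, yv), sched, seed=11)
        for k in fed.params.tensors:
            assert np.array_equal(fed.params.tensors[k], loc.params.tensors[k])
            assert np.array_equal(fed.final_params.tensors[k], loc.final_params.tensors[k])
        assert fed.best_round == loc.best_round
        assert fed.selected_lambda == loc.selected_lambda

    def test_homogeneous_full_batch_single_epoch_matches_centralized(self, rng):
        # identical data, full-batch, E=1: the average of client updates is
        # the pooled gradient step, so the trajectory tracks centralized
        # descent to rounding error
        X, y = lasso_problem(rng, n=50)
        spec = LassoBankSpec(8, np.array([0.1, 0.01]))
        sched = FedSchedule(rounds=25, epochs_per_round=1, lr=0.01, batch_size=None)
        fed = run_fedavg(spec, [((X, y), None)] * 4, sched, seed=0)
        cen = train_local(spec, (X, y), None, sched, seed=0)
        for k in fed.final_params.tensors:
            diff = np.abs(fed.final_params.tensors[k] - cen.final_params.tensors[k]).max()
            assert diff <= 1e-10


class TestSchedules:
    def test_total_epochs_accounting(self):
        s1 = FedSchedule.from_total_epochs(32, 1, 0.1)
        s2 = FedSchedule.from_total_epochs(32, 32, 0.1)
        assert s1.total_epochs == s2.total_epochs == 32
        assert (s1.rounds, s2.rounds) == (32, 1)

    def test_invalid_divisibility_rejected(self):
        with pytest.raises(ValueError):
            FedSchedule.from_total_epochs(30, 4, 0.1)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            FedSchedule(rounds=0, epochs_per_round=1, lr=0.1)


class TestLambdaSelect:
    def _log(self, r, losses):
        return RoundLog(r, [0.0], [0.0], np.asarray(losses, dtype=float), 0, 0.0)

    def test_argmin_at_final_round(self):
        logs = [self._log(1, [0.5, 0.2, 0.9])]
        assert federated_lambda_select(logs) == (1, 1)

    def test_tie_prefers_larger_lambda(self):
        # equal losses at indices 2 and 3: the larger lambda (smaller index
        # on the decreasing grid) wins
        logs = [self._log(1, [0.9, 0.8, 0.3, 0.3])]
        assert federated_lambda_select(logs)[0] == 2

    def test_tie_prefers_earlier_round(self):
        logs = [self._log(1, [0.4, 0.9]), self._log(2, [0.4, 0.9])]
        assert federated_lambda_select(logs) == (0, 1)

    def test_no_rounds_rejected(self):
        with pytest.raises(ValueError):
            federated_lambda_select([])

    def test_validation_weighting_by_client_size(self, rng):
        # aggregate equals 0.1 * loss_A + 0.9 * loss_B for val sizes (10, 90)
        from fedgen.fedtrain import _aggregate_val

        class Fake:
            def val_loss(self, params, data):
                return float(data[1][0])

        clients = [
            (None, (None, np.full(10, 4.0))),
            (None, (None, np.full(90, 1.0))),
        ]
        agg = _aggregate_val(Fake(), None, clients)
        assert agg == pytest.approx(0.1 * 4.0 + 0.9 * 1.0)


class TestCommCost:
    def test_printed_arithmetic_mlp(self):
        spec = MLPSpec(20, (800, 200), 26)
        params = spec.init_params(0)
        sched = FedSchedule(rounds=512, epochs_per_round=32, lr=0.1)
        curve = model_comm_cost(params, sched, n_clients=5, bytes_per_value=4)
        assert curve[-1] == 2 * 5 * 182_226 * 4 * 512
        assert len(curve) == 512

    def test_doubling_rounds_doubles_bytes(self):
        spec = LassoBankSpec(10, np.array([0.1]))
        params = spec.init_params()
        c1 = model_comm_cost(params, FedSchedule(8, 1, 0.1), 3)
        c2 = model_comm_cost(params, FedSchedule(16, 1, 0.1), 3)
        assert c2[-1] == 2 * c1[-1]

    def test_zero_clients_zero_cost(self):
        spec = LassoBankSpec(10, np.array([0.1]))
        curve = model_comm_cost(spec.init_params(), FedSchedule(4, 1, 0.1), 0)
        assert np.all(curve == 0)

    def test_cumulative_bytes_nondecreasing_in_logs(self, rng):
        X, y = lasso_problem(rng)
        spec = LassoBankSpec(8, np.array([0.1]))
        sched = FedSchedule(rounds=5, epochs_per_round=1, lr=0.01, batch_size=16)
        res = run_fedavg(spec, [((X, y), (X, y))] * 2, sched, seed=0)
        bytes_seq = [log.cum_bytes for log in res.logs]
        assert all(b > a for a, b in zip(bytes_seq, bytes_seq[1:]))


def test_round_table_and_summary(rng):
    X, y = lasso_problem(rng)
    spec = LassoBankSpec(8, np.array([0.1]))
    sched = FedSchedule(rounds=3, epochs_per_round=2, lr=0.01, batch_size=16)
    res = run_fedavg(spec, [((X, y), (X, y))] * 2, sched, seed=0)
    table = res.round_table()
    assert list(table["round"]) == [1, 2, 3]
    assert "best aggregated validation loss" in res.summary()


def test_more_local_epochs_help_under_fixed_round_budget():
    # with communication capped at a few rounds, longer local training per
    # round reaches a better validation state than a single epoch per round
    from fedgen.models import MLPSpec, accuracy

    rng = np.random.default_rng(0)
    centers = rng.normal(scale=3.0, size=(10, 6))
    clients, val_X, val_y = [], [], []
    for k in range(5):
        cls = [2 * k, 2 * k + 1]  # heterogeneous: two classes per client
        X = np.vstack([centers[c] + rng.normal(size=(40, 6)) for c in cls])
        y = np.repeat(cls, 40)
        Xv = np.vstack([centers[c] + rng.normal(size=(10, 6)) for c in cls])
        yv = np.repeat(cls, 10)
        clients.append(((X, y), (Xv, yv)))
        val_X.append(Xv)
        val_y.append(yv)
    val_X, val_y = np.vstack(val_X), np.concatenate(val_y)
    spec = MLPSpec(6, (32, 16), 10)
    for rounds in (4, 8):
        results = {}
        for epochs in (1, 8):
            sched = FedSchedule(rounds=rounds, epochs_per_round=epochs, lr=0.05, batch_size=32)
            res = run_fedavg(spec, clients, sched, seed=10)
            results[epochs] = (
                accuracy(val_y, spec.predict(res.final_params, val_X)),
                res.final_val_loss,
            )
        assert results[8][0] >= results[1][0]  # accuracy no worse
        assert results[8][1] < results[1][1]   # loss strictly better
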