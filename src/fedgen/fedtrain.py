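"""Federated averaging engine, simulated in-process.

One communication round broadcasts the global parameters to every client,
runs ``E`` local epochs of seeded mini-batch gradient descent per client in
isolation, and replaces the global parameters with the sample-size-weighted
average of the client results. All clients participate every round
(cross-silo federation); "parallel" client execution is a semantic contract
— no state crosses clients within a round — not a concurrency feature.

Conventions that make trajectories reproducible and degenerate cases exact:

* the batch-shuffling generator of client ``k`` in round ``r`` is seeded
  from ``(seed, k, r)``, so single-client federation is bit-identical to
  local training under the same seed;
* learning-rate decay follows a *global* epoch counter across rounds, so a
  schedule of R rounds x E epochs consumes exactly the same learning-rate
  sequence as R*E epochs of local training;
* model selection keeps the parameters whose aggregated validation loss
  (weighted by client validation counts) is best over rounds; for LASSO
  banks the aggregate is per-lambda and the best (round, lambda) pair is
  selected, ties resolved toward the larger lambda and then the earlier
  round.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ModelParams

log = logging.getLogger("fedgen")

__all__ = [
    "FedSchedule",
    "RoundLog",
    "fedavg_aggregate",
    "client_rng",
    "client_update",
    "run_fedavg",
    "train_local",
    "federated_lambda_select",
    "model_comm_cost",
    "FedAvg",
    "FedAvgResults",
]


@dataclass
class FedSchedule:
    """The knobs of one federated run: R rounds of E local epochs with
    learning rate ``lr`` decaying by ``decay`` per (global) epoch."""

    rounds: int
    epochs_per_round: int
    lr: float
    decay: float = 1.0
    batch_size: int | None = None

    def __post_init__(self) -> None:
        if self.rounds < 1 or self.epochs_per_round < 1:
            raise ValueError("rounds and epochs_per_round must be >= 1")
        if self.lr < 0:
            raise ValueError("learning rate must be nonnegative")

    @property
    def total_epochs(self) -> int:
        return self.rounds * self.epochs_per_round

    @classmethod
    def from_total_epochs(
        cls, total_epochs: int, epochs_per_round: int, lr: float,
        decay: float = 1.0, batch_size: int | None = None,
    ) -> "FedSchedule":
        if total_epochs % epochs_per_round:
            raise ValueError("total epochs must be a multiple of epochs per round")
        return cls(total_epochs // epochs_per_round, epochs_per_round, lr, decay, batch_size)


@dataclass
class RoundLog:
    round: int
    client_loss_pre: list[float]
    client_loss_post: list[float]
    val_loss: np.ndarray | float  # aggregated; per-lambda vector for banks
    cum_bytes: int
    wall_clock: float

    @property
    def val_scalar(self) -> float:
        v = np.asarray(self.val_loss)
        return float(v.min()) if v.ndim else float(v)


def fedavg_aggregate(client_params: list[ModelParams], n_k: np.ndarray) -> ModelParams:
    """Sample-size-weighted elementwise average of client parameters."""
    if not client_params:
        raise ValueError("need at least one client")
    n_k = np.asarray(n_k, dtype=np.float64)
    if n_k.shape != (len(client_params),) or np.any(n_k <= 0):
        raise ValueError("need one positive size per client")
    ref = client_params[0]
    for p in client_params[1:]:
        if p.kind != ref.kind or [v.shape for v in p.tensors.values()] != [
            v.shape for v in ref.tensors.values()
        ]:
            raise ValueError("client parameters are not conformable")
    w = [float(x) for x in n_k / n_k.sum()]  # python floats keep client dtype
    out = {
        key: sum(w[k] * client_params[k].tensors[key] for k in range(len(w)))
        for key in ref.tensors
    }
    return ModelParams(ref.kind, out)


def client_rng(seed: int, client: int, round_index: int) -> np.random.Generator:
    """Batch-shuffling generator for (client, round) — the documented seed
    convention behind all trajectory-equality guarantees."""
    return np.random.default_rng([seed, client, round_index])


def client_update(
    spec,
    params: ModelParams,
    data: tuple[np.ndarray, np.ndarray],
    epochs: int,
    lrs: np.ndarray,
    batch_size: int | None,
    rng: np.random.Generator,
) -> ModelParams:
    """E local epochs of seeded mini-batch descent from the received
    parameters; the input is never mutated."""
    if len(data[1]) == 0:
        raise ValueError("client has an empty training set")
    new = params.copy()
    for e in range(epochs):
        new = spec.train_epoch(new, data, float(lrs[e]), batch_size, rng)
    return new


def _aggregate_val(spec, params, clients) -> np.ndarray | float:
    """Validation loss aggregated over clients, weighted by val counts."""
    losses, weights = [], []
    for train, val in clients:
        if val is None or len(val[1]) == 0:
            continue
        losses.append(np.asarray(spec.val_loss(params, val), dtype=np.float64))
        weights.append(len(val[1]))
    if not losses:
        return float("nan")
    w = np.asarray(weights, dtype=np.float64)
    w /= w.sum()
    agg = sum(wi * li for wi, li in zip(w, losses))
    return agg if np.ndim(agg) else float(agg)


def run_fedavg(
    spec,
    clients: list[tuple[tuple, tuple | None]],
    schedule: FedSchedule,
    seed: int = 0,
    bytes_per_value: int = 4,
    init_params: ModelParams | None = None,
    track_client_loss: bool = True,
) -> "FedAvgResults":
    """R rounds of broadcast -> parallel client update -> weighted average.

    ``clients`` is a list of ``(train, val)`` pairs, each a ``(X, y)`` tuple
    (``val`` may be None). Returns the best-checkpoint model by aggregated
    validation loss along with per-round logs. ``track_client_loss`` turns
    the per-round before/after client training losses (the spike diagnostic)
    off to save forward passes.
    """
    if not clients:
        raise ValueError("need at least one client")
    params = init_params.copy() if init_params is not None else spec.init_params(seed)
    n_k = np.array([len(train[1]) for train, _ in clients], dtype=np.float64)
    size = params.n_values
    E = schedule.epochs_per_round
    logs: list[RoundLog] = []
    best_loss = np.inf
    best_params = params.copy()
    best_round = 0
    best_lambda = 0
    cum_bytes = 0
    t0 = time.perf_counter()
    for r in range(1, schedule.rounds + 1):
        lrs = schedule.lr * schedule.decay ** (
            (r - 1) * E + np.arange(E, dtype=np.float64)
        )
        pre = (
            [float(np.min(spec.train_loss(params, train))) for train, _ in clients]
            if track_client_loss
            else [float("nan")] * len(clients)
        )
        updated = [
            client_update(
                spec, params, train, E, lrs, schedule.batch_size, client_rng(seed, k, r)
            )
            for k, (train, _) in enumerate(clients)
        ]
        post = (
            [
                float(np.min(spec.train_loss(p, train)))
                for p, (train, _) in zip(updated, clients)
            ]
            if track_client_loss
            else [float("nan")] * len(clients)
        )
        params = fedavg_aggregate(updated, n_k)
        cum_bytes += 2 * len(clients) * size * bytes_per_value
        val = _aggregate_val(spec, params, clients)
        scalar = float(np.min(val)) if np.ndim(val) else float(val)
        if np.isfinite(scalar) and scalar < best_loss:
            best_loss = scalar
            best_params = params.copy()
            best_round = r
            best_lambda = int(np.argmin(val)) if np.ndim(val) else 0
        logs.append(
            RoundLog(r, pre, post, val, cum_bytes, time.perf_counter() - t0)
        )
        log.debug(
            "round=%d client_loss_pre=%s client_loss_post=%s val_loss=%.6g cum_bytes=%d",
            r, np.round(pre, 6).tolist(), np.round(post, 6).tolist(), scalar, cum_bytes,
        )
    return FedAvgResults(
        spec=spec,
        params=best_params,
        final_params=params,
        logs=logs,
        best_round=best_round,
        selected_lambda=best_lambda,
        schedule=schedule,
    )


def train_local(
    spec,
    train: tuple,
    val: tuple | None,
    schedule: FedSchedule,
    seed: int = 0,
    client_index: int = 0,
    init_params: ModelParams | None = None,
) -> "FedAvgResults":
    """Non-federated training: the same round structure, learning-rate
    sequence and per-round seed convention as :func:`run_fedavg`, but with a
    single data holder and *no aggregation step*. Single-client federation
    must reproduce this trajectory bit-for-bit (the averaging with weight
    1.0 is a no-op)."""
    params = init_params.copy() if init_params is not None else spec.init_params(seed)
    E = schedule.epochs_per_round
    best_loss, best_params, best_round, best_lambda = np.inf, params.copy(), 0, 0
    logs: list[RoundLog] = []
    t0 = time.perf_counter()
    for r in range(1, schedule.rounds + 1):
        lrs = schedule.lr * schedule.decay ** (
            (r - 1) * E + np.arange(E, dtype=np.float64)
        )
        params = client_update(
            spec, params, train, E, lrs, schedule.batch_size,
            client_rng(seed, client_index, r),
        )
        val_loss = _aggregate_val(spec, params, [(train, val)])
        scalar = float(np.min(val_loss)) if np.ndim(val_loss) else float(val_loss)
        if np.isfinite(scalar) and scalar < best_loss:
            best_loss = scalar
            best_params = params.copy()
            best_round = r
            best_lambda = int(np.argmin(np.atleast_1d(val_loss)))
        logs.append(
            RoundLog(r, [np.nan], [np.nan], val_loss, 0, time.perf_counter() - t0)
        )
    return FedAvgResults(
        spec=spec, params=best_params, final_params=params, logs=logs,
        best_round=best_round, selected_lambda=best_lambda, schedule=schedule,
    )


def federated_lambda_select(logs: list[RoundLog]) -> tuple[int, int]:
    """Best (lambda index, round) over all completed rounds by aggregated
    validation loss; ties prefer the larger lambda (smaller index on the
    decreasing grid), then the earlier round."""
    if not logs:
        raise ValueError("no completed rounds")
    best = (np.inf, 0, 0)
    for log in logs:
        v = np.atleast_1d(np.asarray(log.val_loss, dtype=np.float64))
        idx = int(np.argmin(v))  # argmin takes the smallest index on ties
        if v[idx] < best[0]:
            best = (float(v[idx]), idx, log.round)
    return best[1], best[2]


def model_comm_cost(
    params: ModelParams, schedule: FedSchedule, n_clients: int, bytes_per_value: int = 4
) -> np.ndarray:
    """Cumulative communication curve over rounds: each round moves the full
    parameter set down to and back up from every client."""
    per_round = 2 * n_clients * params.n_values * bytes_per_value
    return per_round * np.arange(1, schedule.rounds + 1, dtype=np.int64)


# ---------------------------------------------------------------------------
# Model-style wrapper


class FedAvg:
    """Federated averaging as a fit-able model over client datasets."""

    def __init__(self, spec, clients, schedule: FedSchedule, seed: int = 0) -> None:
        self.spec = spec
        self.clients = clients
        self.schedule = schedule
        self.seed = seed

    def fit(self) -> "FedAvgResults":
        return run_fedavg(self.spec, self.clients, self.schedule, seed=self.seed)


@dataclass
class FedAvgResults:
    """Outcome of a federated run: the selected checkpoint, the last-round
    parameters, and one log entry per communication round."""

    spec: object
    params: ModelParams
    final_params: ModelParams
    logs: list[RoundLog]
    best_round: int
    selected_lambda: int
    schedule: FedSchedule

    def round_table(self) -> pd.DataFrame:
        rows = []
        for log in self.logs:
            rows.append(
                {
                    "round": log.round,
                    "mean_client_loss_pre": float(np.mean(log.client_loss_pre)),
                    "mean_client_loss_post": float(np.mean(log.client_loss_post)),
                    "val_loss": log.val_scalar,
                    "cum_bytes": log.cum_bytes,
                    "wall_clock": log.wall_clock,
                }
            )
        return pd.DataFrame(rows)

    @property
    def final_val_loss(self) -> float:
        return self.logs[-1].val_scalar if self.logs else float("nan")

    @property
    def best_val_loss(self) -> float:
        return min((log.val_scalar for log in self.logs), default=float("nan"))

    def spike_fraction(self) -> float:
        """Fraction of round boundaries where the freshly aggregated model
        scores worse on clients' training data than the locally fitted one
        (the post-aggregation loss spike characteristic of client drift)."""
        if len(self.logs) < 2:
            return float("nan")
        hits = 0
        total = 0
        for prev, cur in zip(self.logs, self.logs[1:]):
            pre = np.asarray(cur.client_loss_pre)
            post = np.asarray(prev.client_loss_post)
            if np.isnan(pre).any() or np.isnan(post).any():
                return float("nan")  # client losses were not tracked
            hits += int(np.mean(pre) > np.mean(post))
            total += 1
        return hits / total

    def summary(self) -> str:
        lines = [
            "FedAvg run",
            f"  clients: {len(self.logs[0].client_loss_pre) if self.logs else 0}"
            f"  rounds: {self.schedule.rounds}"
            f"  epochs/round: {self.schedule.epochs_per_round}",
            f"  best aggregated validation loss {self.best_val_loss:.5g} "
            f"at round {self.best_round}",
            f"  communication: {self.logs[-1].cum_bytes if self.logs else 0} bytes",
        ]
        return "\n".join(lines)
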