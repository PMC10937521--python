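"""Cross-validation harness and the three study designs.

* :func:`run_phenotype_experiment` — local vs federated vs centralized
  polygenic prediction on the many-node, low-heterogeneity regime: per-node
  GWAS feature selection (local, meta-analyzed, centralized), LASSO banks
  trained in each mode, all evaluated on one merged test set per fold.
* :func:`run_ancestry_experiment` — the communication sweep on the few-node
  heterogeneous regime: federated PCA for a shared 20-PC feature space, then
  FedAvg MLPs at fixed total epochs with 1..32 local epochs per round.
* :func:`run_pca_sweep` — federated vs centralized PCA as the input variant
  set grows (by relaxing pruning), judged by a fixed downstream classifier.

Everything fold-dependent (GWAS, meta-analysis, lambda_max, feature
standardization and imputation means, PCA centering and loadings) is
computed from training folds only; validation and test rows are only ever
transformed. Default problem sizes are desk-scale: small enough that the
full designs run on a single CPU in minutes, large enough that the expected
model orderings emerge from the simulated signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import synthetic
from .assoc import gwas_node, meta_random_effects, select_top_snps
from .datatypes import GenotypeBlock, NodeDataset
from .fedpca import FederatedPCA, centralized_pca, project
from .fedtrain import FedSchedule, run_fedavg, train_local
from .models import (
    LassoBankSpec,
    MLPSpec,
    accuracy,
    lambda_max,
    make_lambda_grid,
    r2_score,
)
from .qc import QCThresholds, ld_prune, run_qc, variant_union

__all__ = [
    "PhenotypeStudyConfig",
    "AncestryStudyConfig",
    "ExperimentResult",
    "assign_folds",
    "fold_masks",
    "quantile_interval",
    "run_phenotype_experiment",
    "run_ancestry_experiment",
    "run_pca_sweep",
    "report",
]


# ---------------------------------------------------------------------------
# folds and summaries


def assign_folds(
    nodes: list[NodeDataset], n_folds: int = 10, seed: int = 0
) -> list[NodeDataset]:
    """Random per-node partition into ``n_folds`` folds of near-equal size
    (sizes differ by at most one). Deterministic given the seed."""
    out = []
    for i, node in enumerate(nodes):
        if node.n_samples < n_folds:
            raise ValueError(
                f"node {node.node_id} has {node.n_samples} samples < {n_folds} folds"
            )
        rng = np.random.default_rng([seed, i])
        order = rng.permutation(node.n_samples)
        folds = np.empty(node.n_samples, dtype=np.int64)
        for f, chunk in enumerate(np.array_split(order, n_folds)):
            folds[chunk] = f
        out.append(NodeDataset(node.node_id, node.block, node.phenotypes, folds))
    return out


def fold_masks(folds: np.ndarray, t: int, n_folds: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CV rotation for iteration ``t``: test = fold t, validation = fold
    (t+1) mod n, train = the rest. Returns (train, val, test) masks."""
    test = folds == t
    val = folds == (t + 1) % n_folds
    train = ~(test | val)
    return train, val, test


def quantile_interval(values: np.ndarray, mode: str = "linear") -> tuple[float, float, float]:
    """(median, q10, q90). ``linear`` interpolates the empirical CDF;
    ``drop-extremes`` uses the 2nd smallest/largest of the values."""
    v = np.sort(np.asarray(values, dtype=np.float64))
    med = float(np.median(v))
    if mode == "linear":
        return med, float(np.quantile(v, 0.1)), float(np.quantile(v, 0.9))
    if mode == "drop-extremes":
        if len(v) < 3:
            return med, float(v[0]), float(v[-1])
        return med, float(v[1]), float(v[-2])
    raise ValueError("mode must be 'linear' or 'drop-extremes'")


@dataclass
class ExperimentResult:
    """Long-format metric table plus experiment-specific extras."""

    table: pd.DataFrame
    extras: dict = field(default_factory=dict)

    def summarize(
        self, by: tuple[str, ...] = ("model",), value: str = "value", mode: str = "linear"
    ) -> pd.DataFrame:
        if self.table.empty:
            return pd.DataFrame(columns=[*by, "median", "q10", "q90"])
        rows = []
        for key, grp in self.table.groupby(list(by), sort=False):
            key = key if isinstance(key, tuple) else (key,)
            med, lo, hi = quantile_interval(grp[value].to_numpy(), mode)
            rows.append({**dict(zip(by, key)), "median": med, "q10": lo, "q90": hi})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# feature construction


@dataclass
class FeatureSpace:
    """Training-fold-derived feature transform: a variant-id list, per-variant
    imputation means, and standardization moments over [SNPs, age, sex]."""

    ids: list[str]
    impute: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    def transform(self, node: NodeDataset, rows: np.ndarray) -> np.ndarray:
        block = node.block.subset_by_variant_id(self.ids)
        x = block.dosages_float(impute=self.impute)[rows]
        covs = node.phenotypes[["age", "sex"]].to_numpy(dtype=np.float64)[rows]
        full = np.column_stack([x, covs])
        return (full - self.mean) / self.sd


def _fit_feature_space(
    nodes: list[NodeDataset], train_masks: list[np.ndarray], ids: list[str]
) -> FeatureSpace:
    """Imputation and standardization moments from pooled training rows
    (one (sum, sumsq, count) aggregation in the federated reading)."""
    sums = np.zeros(len(ids) + 2)
    sumsq = np.zeros(len(ids) + 2)
    count = 0
    obs_sum = np.zeros(len(ids))
    obs_n = np.zeros(len(ids))
    for node, mask in zip(nodes, train_masks):
        block = node.block.subset_by_variant_id(ids)
        d = block.dosages[mask]
        obs = d != -1
        obs_sum += np.where(obs, d, 0).sum(axis=0)
        obs_n += obs.sum(axis=0)
    impute = np.where(obs_n > 0, obs_sum / np.maximum(obs_n, 1), 0.0)
    for node, mask in zip(nodes, train_masks):
        block = node.block.subset_by_variant_id(ids)
        x = block.dosages_float(impute=impute)[mask]
        covs = node.phenotypes[["age", "sex"]].to_numpy(dtype=np.float64)[mask]
        full = np.column_stack([x, covs])
        sums += full.sum(axis=0)
        sumsq += (full**2).sum(axis=0)
        count += full.shape[0]
    mean = sums / count
    var = np.maximum(sumsq / count - mean**2, 0.0)
    sd = np.sqrt(var)
    sd[sd < 1e-8] = 1.0  # constant columns pass through unscaled
    return FeatureSpace(list(ids), impute, mean, sd)


def _phenotypes(node: NodeDataset, rows: np.ndarray) -> np.ndarray:
    return node.phenotypes["phenotype"].to_numpy(dtype=np.float64)[rows]


# ---------------------------------------------------------------------------
# phenotype experiment


@dataclass
class PhenotypeStudyConfig:
    """Desk-scale many-node quantitative-phenotype study."""

    n_nodes: int = 19
    node_sizes: tuple[int, ...] | int = (120, 250, 420)  # cycled across nodes
    n_variants: int = 2000  # enough markers that KING kinship is calibrated
    n_causal: int = 20
    heritability: float = 0.5
    missing_rate: float = 0.002  # array-scale missingness; the 2% variant
    # filter then trims genuine outliers instead of decimating small nodes
    fst_range: tuple[float, float] = (0.001, 0.01)
    top_snps: int = 50
    gwas_pcs: int = 10
    n_folds: int = 10
    total_epochs: int = 64
    epochs_per_round: int = 8
    lr: float = 5e-3
    decay: float = 0.99
    batch_size: int = 16
    n_lambda: int = 32


def _simulate_phenotype_nodes(
    cfg: PhenotypeStudyConfig, seed: int
) -> list[NodeDataset]:
    model, specs = synthetic.ukb_like_regime(
        cfg.n_nodes, 100, cfg.n_variants, cfg.fst_range
    )
    sizes = cfg.node_sizes
    if isinstance(sizes, int):
        sizes = (sizes,)
    for i, spec in enumerate(specs):
        spec.n_samples = int(sizes[i % len(sizes)])
    freqs = synthetic.draw_population_frequencies(model, seed)
    nodes = synthetic.simulate_genotypes(freqs, specs, cfg.missing_rate, seed + 1, model)
    effects = synthetic.draw_causal_effects(cfg.n_variants, cfg.n_causal, seed + 2)
    trait = synthetic.TraitModel(cfg.n_causal, cfg.heritability)
    return synthetic.simulate_phenotypes(nodes, trait, effects, seed + 3)


def _qc_and_harmonize(nodes: list[NodeDataset], order: str) -> list[NodeDataset]:
    """Per-node QC, then restriction to the variants every node kept (models
    need a shared candidate space; the meta-analysis itself would tolerate
    partial overlap)."""
    cleaned = []
    for node in nodes:
        block, rep = run_qc(node.block, QCThresholds(), order=order)
        kept_samples = rep.samples.set_index("sample_id")["kept"]
        mask = kept_samples.loc[node.phenotypes["sample_id"]].to_numpy()
        cleaned.append(node.with_block(block, np.flatnonzero(mask)))
    shared = set(cleaned[0].block.variant_ids)
    for node in cleaned[1:]:
        shared &= set(node.block.variant_ids)
    catalog = [v for v in cleaned[0].block.variant_ids if v in shared]
    return [n.with_block(n.block.subset_by_variant_id(catalog)) for n in cleaned]


def _ols_baseline(X_tr: np.ndarray, y_tr: np.ndarray, X_te: np.ndarray) -> np.ndarray:
    A = np.column_stack([np.ones(len(y_tr)), X_tr])
    coef, *_ = np.linalg.lstsq(A, y_tr, rcond=None)
    return np.column_stack([np.ones(len(X_te)), X_te]) @ coef


def run_phenotype_experiment(
    cfg: PhenotypeStudyConfig | None = None, seed: int = 0
) -> ExperimentResult:
    """Local vs federated vs centralized polygenic prediction, 10-fold CV.

    Per fold: per-node GWAS on the training folds (age, sex and within-node
    genotype PCs as covariates), random-effects meta-analysis, top-SNP
    selection (locally, from the meta-analysis, and from a pooled
    centralized GWAS), then LASSO banks trained locally per node, federated
    with FedAvg, and centralized — all tested on the merged test fold.
    Returns per-(model, node, fold) test R^2.
    """
    cfg = cfg or PhenotypeStudyConfig()
    nodes = _simulate_phenotype_nodes(cfg, seed)
    nodes = _qc_and_harmonize(nodes, order="samples_first")
    nodes = assign_folds(nodes, cfg.n_folds, seed + 10)
    rows = []
    for t in range(cfg.n_folds):
        masks = [fold_masks(n.folds, t, cfg.n_folds) for n in nodes]
        train_masks = [m[0] for m in masks]
        stats = [
            gwas_node(n, n_pcs=cfg.gwas_pcs, sample_mask=m)
            for n, m in zip(nodes, train_masks)
        ]
        meta = meta_random_effects(stats)
        ids_meta = select_top_snps(meta, cfg.top_snps)
        ids_central = select_top_snps(_centralized_gwas(nodes, train_masks, cfg), cfg.top_snps)

        fs_meta = _fit_feature_space(nodes, train_masks, ids_meta)
        fs_central = _fit_feature_space(nodes, train_masks, ids_central)

        schedule = FedSchedule.from_total_epochs(
            cfg.total_epochs, cfg.epochs_per_round, cfg.lr, cfg.decay, cfg.batch_size
        )
        y_test = np.concatenate([_phenotypes(n, m[2]) for n, m in zip(nodes, masks)])

        # federated model on meta-GWAS features
        clients = []
        for n, (tr, va, _te) in zip(nodes, masks):
            clients.append(
                (
                    (fs_meta.transform(n, tr), _phenotypes(n, tr)),
                    (fs_meta.transform(n, va), _phenotypes(n, va)),
                )
            )
        lam_fed = make_lambda_grid(
            _pooled_lambda_max(clients), cfg.n_lambda
        )
        spec_fed = LassoBankSpec(len(ids_meta) + 2, lam_fed)
        res_fed = run_fedavg(spec_fed, clients, schedule, seed=seed + 100 + t)
        X_test_meta = np.vstack(
            [fs_meta.transform(n, m[2]) for n, m in zip(nodes, masks)]
        )
        pred = spec_fed.predict(res_fed.params, X_test_meta, res_fed.selected_lambda)
        rows.append((t, "federated", "all", r2_score(y_test, pred)))

        # centralized model on centralized-GWAS features
        Xc_tr = np.vstack([fs_central.transform(n, m[0]) for n, m in zip(nodes, masks)])
        yc_tr = np.concatenate([_phenotypes(n, m[0]) for n, m in zip(nodes, masks)])
        Xc_va = np.vstack([fs_central.transform(n, m[1]) for n, m in zip(nodes, masks)])
        yc_va = np.concatenate([_phenotypes(n, m[1]) for n, m in zip(nodes, masks)])
        lam_c = make_lambda_grid(lambda_max(Xc_tr, yc_tr), cfg.n_lambda)
        spec_c = LassoBankSpec(Xc_tr.shape[1], lam_c)
        res_c = train_local(
            spec_c, (Xc_tr, yc_tr), (Xc_va, yc_va), schedule, seed=seed + 200 + t
        )
        Xc_te = np.vstack([fs_central.transform(n, m[2]) for n, m in zip(nodes, masks)])
        pred = spec_c.predict(res_c.params, Xc_te, res_c.selected_lambda)
        rows.append((t, "centralized", "all", r2_score(y_test, pred)))

        # covariates-only centralized baseline (age, sex)
        cov_tr = np.vstack(
            [n.phenotypes[["age", "sex"]].to_numpy(float)[m[0]] for n, m in zip(nodes, masks)]
        )
        cov_te = np.vstack(
            [n.phenotypes[["age", "sex"]].to_numpy(float)[m[2]] for n, m in zip(nodes, masks)]
        )
        pred = _ols_baseline(cov_tr, yc_tr, cov_te)
        rows.append((t, "covariates_centralized", "all", r2_score(y_test, pred)))

        # local models: native (local-GWAS) and meta-GWAS features
        for k, (n, (tr, va, te)) in enumerate(zip(nodes, masks)):
            ids_local = select_top_snps(stats[k], min(cfg.top_snps, len(stats[k])))
            for label, ids in (("local_local", ids_local), ("local_meta", ids_meta)):
                fs_k = _fit_feature_space([n], [tr], ids)
                X_tr, y_tr = fs_k.transform(n, tr), _phenotypes(n, tr)
                X_va, y_va = fs_k.transform(n, va), _phenotypes(n, va)
                lam_k = make_lambda_grid(lambda_max(X_tr, y_tr), cfg.n_lambda)
                spec_k = LassoBankSpec(X_tr.shape[1], lam_k)
                res_k = train_local(
                    spec_k, (X_tr, y_tr), (X_va, y_va), schedule,
                    seed=seed + 300 + t, client_index=k,
                )
                X_te_all = np.vstack(
                    [fs_k.transform(nn, mm[2]) for nn, mm in zip(nodes, masks)]
                )
                pred = spec_k.predict(res_k.params, X_te_all, res_k.selected_lambda)
                rows.append((t, label, n.node_id, r2_score(y_test, pred)))
            # per-node covariates-only baseline
            cov_tr_k = n.phenotypes[["age", "sex"]].to_numpy(float)[tr]
            pred = _ols_baseline(cov_tr_k, _phenotypes(n, tr), cov_te)
            rows.append((t, "covariates_local", n.node_id, r2_score(y_test, pred)))

    table = pd.DataFrame(rows, columns=["fold", "model", "node", "value"])
    sizes = {n.node_id: int(n.n_samples) for n in nodes}
    return ExperimentResult(table, extras={"node_sizes": sizes, "metric": "r2"})


def _pooled_lambda_max(clients) -> float:
    X = np.vstack([c[0][0] for c in clients])
    y = np.concatenate([c[0][1] for c in clients])
    return lambda_max(X, y)


def _centralized_gwas(nodes, train_masks, cfg) -> pd.DataFrame:
    pooled_block = GenotypeBlock(
        np.vstack([n.block.dosages for n in nodes]),
        nodes[0].block.variants.copy(),
        pd.concat([n.block.samples for n in nodes], ignore_index=True),
    )
    pooled_phen = pd.concat([n.phenotypes for n in nodes], ignore_index=True)
    pooled = NodeDataset("pooled", pooled_block, pooled_phen)
    mask = np.concatenate(train_masks)
    return gwas_node(pooled, n_pcs=cfg.gwas_pcs, sample_mask=mask)


# ---------------------------------------------------------------------------
# ancestry experiment


@dataclass
class AncestryStudyConfig:
    """Desk-scale few-node heterogeneous ancestry study."""

    node_sizes: tuple[int, ...] = (80, 62, 70, 74, 78)
    n_variants: int = 2000
    missing_rate: float = 0.002
    subpop_fst: tuple[float, float] = (0.05, 0.15)
    superpop_fst: float = 0.12
    prune_window: int = 50
    prune_step: int = 5
    prune_r2_max: float = 0.1
    pca_max_snps: int = 300  # pruning-strictness budget for the shared PC space
    n_pcs: int = 20
    hidden: tuple[int, int] = (800, 200)
    n_folds: int = 10
    total_epochs: int = 512
    epochs_per_round_sweep: tuple[int, ...] = (1, 2, 4, 8, 16, 32)
    lr: float = 0.1
    decay: float = 0.9999
    batch_size: int = 64


def _simulate_ancestry_nodes(cfg: AncestryStudyConfig, seed: int) -> tuple[list[NodeDataset], list[str]]:
    model, specs = synthetic.thousand_genomes_like_regime(
        cfg.node_sizes, cfg.n_variants, cfg.subpop_fst, cfg.superpop_fst
    )
    freqs = synthetic.draw_population_frequencies(model, seed)
    nodes = synthetic.simulate_genotypes(freqs, specs, cfg.missing_rate, seed + 1, model)
    nodes = [_qc_one(node) for node in nodes]
    # variants must agree across nodes before pruning (array-style data);
    # keep the intersection of per-node QC survivors
    shared = set(nodes[0].block.variant_ids)
    for n in nodes[1:]:
        shared &= set(n.block.variant_ids)
    catalog = [v for v in nodes[0].block.variant_ids if v in shared]
    nodes = [n.with_block(n.block.subset_by_variant_id(catalog)) for n in nodes]
    # shared variant space: per-node pruning, then the union of survivors
    kept_lists = [
        ld_prune(n.block, cfg.prune_window, cfg.prune_step, cfg.prune_r2_max)
        for n in nodes
    ]
    union = variant_union(kept_lists, catalog=nodes[0].block.variant_ids)
    if cfg.pca_max_snps:
        union = union[: cfg.pca_max_snps]
    nodes = [n.with_block(n.block.subset_by_variant_id(union)) for n in nodes]
    classes = sorted(model.population_names)
    return nodes, classes


def _qc_one(node: NodeDataset) -> NodeDataset:
    block, rep = run_qc(node.block, QCThresholds(), order="variants_first")
    kept = rep.samples.set_index("sample_id")["kept"]
    mask = kept.loc[node.phenotypes["sample_id"]].to_numpy()
    return node.with_block(block, np.flatnonzero(mask))


def _standardize_scores(
    scores: list[np.ndarray], train_masks: list[np.ndarray]
) -> list[np.ndarray]:
    """Per-PC standardization from pooled training rows (one federated
    (sum, sumsq, count) aggregation); keeps the classifier's input scale
    independent of the variant count behind the PCA."""
    tr = np.vstack([sc[m] for sc, m in zip(scores, train_masks)])
    mean = tr.mean(axis=0)
    sd = tr.std(axis=0)
    sd[sd < 1e-8] = 1.0
    return [(sc - mean) / sd for sc in scores]


def _labels(node: NodeDataset, classes: list[str]) -> np.ndarray:
    lut = {c: i for i, c in enumerate(classes)}
    return np.array([lut[p] for p in node.phenotypes["population"]], dtype=np.int64)


def run_ancestry_experiment(
    cfg: AncestryStudyConfig | None = None, seed: int = 0
) -> ExperimentResult:
    """Communication-schedule sweep for federated ancestry classification.

    Per fold: exact federated PCA on the training rows builds the shared
    20-PC space; FedAvg MLPs run at fixed total epochs for each
    epochs-per-round setting; a centralized MLP is the reference. Records
    final aggregated validation loss, merged-validation accuracy,
    post-aggregation spike fractions and communication bytes (model traffic
    plus the federated-PCA bill).
    """
    cfg = cfg or AncestryStudyConfig()
    nodes, classes = _simulate_ancestry_nodes(cfg, seed)
    nodes = assign_folds(nodes, cfg.n_folds, seed + 10)
    labels = [_labels(n, classes) for n in nodes]
    class_super = [c[:3] for c in classes]  # subpop names are SUPER + digit
    rows = []
    curves: dict[int, list[np.ndarray]] = {e: [] for e in cfg.epochs_per_round_sweep}
    for t in range(cfg.n_folds):
        masks = [fold_masks(n.folds, t, cfg.n_folds) for n in nodes]
        train_blocks = [
            n.block.take_samples(np.flatnonzero(m[0])) for n, m in zip(nodes, masks)
        ]
        pca = FederatedPCA(train_blocks, n_pcs=cfg.n_pcs).fit()
        scores = [pca.project(n.block) for n in nodes]
        scores = _standardize_scores(scores, [m[0] for m in masks])
        clients = []
        for sc, lab, (tr, va, _te) in zip(scores, labels, masks):
            clients.append(((sc[tr], lab[tr]), (sc[va], lab[va])))
        spec = MLPSpec(cfg.n_pcs, cfg.hidden, len(classes))
        val_X = np.vstack([sc[m[1]] for sc, m in zip(scores, masks)])
        val_y = np.concatenate([lab[m[1]] for lab, m in zip(labels, masks)])
        for e in cfg.epochs_per_round_sweep:
            schedule = FedSchedule.from_total_epochs(
                cfg.total_epochs, e, cfg.lr, cfg.decay, cfg.batch_size
            )
            res = run_fedavg(
                spec, clients, schedule, seed=seed + 20 + t,
                track_client_loss=(e == max(cfg.epochs_per_round_sweep)),
            )
            acc = accuracy(val_y, spec.predict(res.final_params, val_X))
            rows.append(
                {
                    "fold": t,
                    "model": f"fedavg_E{e}",
                    "epochs_per_round": e,
                    "final_val_loss": res.final_val_loss,
                    "best_val_loss": res.best_val_loss,
                    "value": acc,
                    "spike_fraction": res.spike_fraction(),
                    "comm_bytes": res.logs[-1].cum_bytes + pca.comm_bytes,
                }
            )
            curves[e].append(
                np.array([log.val_scalar for log in res.logs])
            )
        # centralized reference
        tr_X = np.vstack([sc[m[0]] for sc, m in zip(scores, masks)])
        tr_y = np.concatenate([lab[m[0]] for lab, m in zip(labels, masks)])
        schedule = FedSchedule.from_total_epochs(
            cfg.total_epochs, 8, cfg.lr, cfg.decay, cfg.batch_size
        )
        res_c = train_local(spec, (tr_X, tr_y), (val_X, val_y), schedule, seed=seed + 20 + t)
        pred = spec.predict(res_c.final_params, val_X)
        acc = accuracy(val_y, pred)
        super_acc = accuracy(
            np.array([class_super[i] for i in val_y]),
            np.array([class_super[i] for i in pred]),
        )
        rows.append(
            {
                "fold": t,
                "model": "centralized",
                "epochs_per_round": 0,
                "final_val_loss": res_c.final_val_loss,
                "best_val_loss": res_c.best_val_loss,
                "value": acc,
                "spike_fraction": float("nan"),
                "comm_bytes": 0,
                "superpop_accuracy": super_acc,
            }
        )
    table = pd.DataFrame(rows)
    return ExperimentResult(
        table,
        extras={"metric": "accuracy", "classes": classes, "curves": curves},
    )


# ---------------------------------------------------------------------------
# PCA input sweep


def run_pca_sweep(
    cfg: AncestryStudyConfig | None = None,
    seed: int = 0,
    r2_grid: tuple[float, ...] = (0.05, 0.1, 0.3, 1.0),
    classifier_epochs: int = 128,
    n_folds: int | None = 3,
) -> ExperimentResult:
    """Accuracy of a fixed centralized classifier on federated vs
    centralized PCs as the pruned variant set grows."""
    cfg = cfg or AncestryStudyConfig()
    nodes, classes = _simulate_ancestry_nodes(cfg, seed)
    n_folds = n_folds or cfg.n_folds
    nodes = assign_folds(nodes, cfg.n_folds, seed + 10)
    labels = [_labels(n, classes) for n in nodes]
    rows = []
    base_blocks = [n.block for n in nodes]
    for r2_max in r2_grid:
        kept_lists = [
            ld_prune(b, cfg.prune_window, cfg.prune_step, r2_max) for b in base_blocks
        ]
        union = variant_union(kept_lists, catalog=base_blocks[0].variant_ids)
        blocks = [b.subset_by_variant_id(union) for b in base_blocks]
        for t in range(n_folds):
            masks = [fold_masks(n.folds, t, cfg.n_folds) for n in nodes]
            train_blocks = [
                b.take_samples(np.flatnonzero(m[0])) for b, m in zip(blocks, masks)
            ]
            fed = FederatedPCA(train_blocks, n_pcs=cfg.n_pcs).fit()
            cen = centralized_pca(train_blocks, n_pcs=cfg.n_pcs)
            for mode, model in (("federated", fed.model), ("centralized", cen)):
                scores = [project(model, b) for b in blocks]
                scores = _standardize_scores(scores, [m[0] for m in masks])
                tr_X = np.vstack([sc[m[0]] for sc, m in zip(scores, masks)])
                tr_y = np.concatenate([lab[m[0]] for lab, m in zip(labels, masks)])
                va_X = np.vstack([sc[m[1]] for sc, m in zip(scores, masks)])
                va_y = np.concatenate([lab[m[1]] for lab, m in zip(labels, masks)])
                spec = MLPSpec(cfg.n_pcs, cfg.hidden, len(classes))
                schedule = FedSchedule.from_total_epochs(
                    classifier_epochs, 8, cfg.lr, cfg.decay, cfg.batch_size
                )
                res = train_local(spec, (tr_X, tr_y), (va_X, va_y), schedule, seed=seed + t)
                for split, (X, y) in (
                    ("train", (tr_X, tr_y)),
                    ("validation", (va_X, va_y)),
                ):
                    rows.append(
                        {
                            "fold": t,
                            "n_snps": len(union),
                            "pca": mode,
                            "split": split,
                            "value": accuracy(y, spec.predict(res.final_params, X)),
                        }
                    )
    return ExperimentResult(pd.DataFrame(rows), extras={"metric": "accuracy"})


# ---------------------------------------------------------------------------
# reporting


def report(result: ExperimentResult, out_dir) -> list[str]:
    """Write the metric table, its median/quantile summary and a figure.

    Returns the list of files written; an empty result produces an empty
    report with a warning.
    """
    import warnings
    from pathlib import Path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    table_path = out / "metrics.tsv"
    result.table.to_csv(table_path, sep="\t", index=False)
    written.append(str(table_path))
    if result.table.empty:
        warnings.warn("empty experiment result; writing empty report")
        return written
    by = ("model",) if "model" in result.table.columns else tuple(
        c for c in ("pca", "split", "n_snps") if c in result.table.columns
    )
    summary = result.summarize(by=by)
    summary_path = out / "summary.tsv"
    summary.to_csv(summary_path, sep="\t", index=False)
    written.append(str(summary_path))
    fig, ax = plt.subplots(figsize=(7, 4))
    labels, meds, los, his = [], [], [], []
    for _, row in summary.iterrows():
        labels.append(" / ".join(str(row[c]) for c in by))
        meds.append(row["median"])
        los.append(row["median"] - row["q10"])
        his.append(row["q90"] - row["median"])
    ax.errorbar(range(len(meds)), meds, yerr=[los, his], fmt="o", capsize=3)
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=7)
    ax.set_ylabel(result.extras.get("metric", "value"))
    ax.set_title("median and 0.1-0.9 quantiles over folds")
    fig.tight_layout()
    fig_path = out / "summary.png"
    fig.savefig(fig_path, dpi=120)
    plt.close(fig)
    written.append(str(fig_path))
    curves = result.extras.get("curves")
    if curves:
        fig, ax = plt.subplots(figsize=(7, 4))
        for e, per_fold in curves.items():
            c = np.median(np.vstack(per_fold), axis=0)
            epochs = np.arange(1, len(c) + 1) * e
            ax.plot(epochs, c, label=f"{e} epochs/round")
        ax.set_xlabel("total local epochs")
        ax.set_ylabel("aggregated validation loss (median over folds)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        curve_path = out / "loss_curves.png"
        fig.savefig(curve_path, dpi=120)
        plt.close(fig)
        written.append(str(curve_path))
    return written
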