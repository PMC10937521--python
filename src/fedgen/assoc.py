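"""Per-node GWAS and cross-node random-effects meta-analysis.

Each node regresses the phenotype on one variant at a time (ordinary least
squares with intercept, age, sex and within-node genotype PCs as
covariates); the resulting per-variant summary statistics (beta, SE, p, n)
are the only cross-node currency. The server pools them per variant with a
DerSimonian-Laird random-effects meta-analysis and selects the most
significant variants as the shared feature space.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeBlock, NodeDataset

__all__ = [
    "genotype_pcs",
    "gwas_node",
    "meta_random_effects",
    "select_top_snps",
]

_P_FLOOR = np.finfo(np.float64).tiny  # two-sided p clamped into (0, 1]


def genotype_pcs(block: GenotypeBlock, n_pcs: int) -> np.ndarray:
    """Within-node PC scores of centered, mean-imputed dosages (n x n_pcs).

    Computed from the smaller Gram matrix (samples x samples or variants x
    variants), which only needs the top ``n_pcs`` eigenpairs.
    """
    from scipy.linalg import eigh

    x = block.dosages_float(impute="mean")
    x = x - x.mean(axis=0)
    n, m = x.shape
    n_pcs = min(n_pcs, min(n, m) - 1)
    if n_pcs <= 0:
        return np.empty((n, 0))
    if n <= m:
        gram = x @ x.T
        vals, vecs = eigh(gram, subset_by_index=[n - n_pcs, n - 1])
        order = np.argsort(vals)[::-1]
        return vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    gram = x.T @ x
    vals, vecs = eigh(gram, subset_by_index=[m - n_pcs, m - 1])
    order = np.argsort(vals)[::-1]
    return x @ vecs[:, order]


def gwas_node(
    node: NodeDataset,
    n_pcs: int = 20,
    sample_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant OLS association on one node's (training) samples.

    For every variant the phenotype is regressed on (dosage, age, sex,
    ``n_pcs`` genotype PCs, intercept); mean-imputed missing dosages. The
    returned table has one row per testable variant: ``variant_id, beta, se,
    p, n`` with beta/se/p for the dosage term and p two-sided from the t
    distribution. Variants whose covariate-adjusted dosage has zero variance
    are skipped.

    ``sample_mask`` restricts the fit (and the PC computation) to a subset,
    typically the training folds.
    """
    block = node.block
    phen = node.phenotypes
    if sample_mask is not None:
        idx = np.flatnonzero(np.asarray(sample_mask))
        block = block.take_samples(idx)
        phen = phen.iloc[idx]
    y = phen["phenotype"].to_numpy(dtype=np.float64)
    n = len(y)
    pcs = genotype_pcs(block, n_pcs)
    covars = np.column_stack(
        [
            np.ones(n),
            phen["age"].to_numpy(dtype=np.float64),
            phen["sex"].to_numpy(dtype=np.float64),
            pcs,
        ]
    )
    q_cov = np.linalg.qr(covars, mode="reduced")[0]
    g = block.dosages_float(impute="mean")
    y_res = y - q_cov @ (q_cov.T @ y)
    g_res = g - q_cov @ (q_cov.T @ g)
    gg = np.einsum("ij,ij->j", g_res, g_res)
    gy = g_res.T @ y_res
    yy = float(y_res @ y_res)
    # a constant (or covariate-determined) phenotype leaves only rounding
    # noise in the residual; report exact nulls instead of noise-driven stats
    if yy <= n * (1e-12 * (1.0 + float(np.mean(y**2)))) ** 2:
        y_res = np.zeros_like(y_res)
        gy = np.zeros_like(gy)
        yy = 0.0
    df = n - covars.shape[1] - 1
    if df <= 0:
        raise ValueError("not enough samples for the covariate model")
    testable = gg > 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(testable, gy / gg, np.nan)
        rss = np.maximum(yy - beta**2 * gg, 0.0)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / gg)
        t = np.where(se > 0, beta / se, np.where(np.abs(beta) > 0, np.inf, 0.0))
        p = 2.0 * stats.t.sf(np.abs(t), df=df)
    p = np.clip(p, _P_FLOOR, 1.0)
    out = pd.DataFrame(
        {
            "variant_id": block.variant_ids,
            "beta": beta,
            "se": se,
            "p": p,
            "n": n,
        }
    )
    return out[testable].reset_index(drop=True)


def meta_random_effects(stats_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """DerSimonian-Laird random-effects meta-analysis across nodes.

    Per variant (matched by id, over the nodes that report it):
    fixed-effect weights ``w_i = 1/se_i^2``; ``Q = sum w_i (b_i - b_FE)^2``;
    ``tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))``; random-effect
    weights ``w*_i = 1/(se_i^2 + tau2)``; pooled beta, pooled
    ``se = (sum w*)^{-1/2}``; p from the normal approximation.

    Returns a table ``variant_id, beta, se, p, tau2, k`` in the order ids
    first appear across the input tables.
    """
    if not stats_tables:
        raise ValueError("need at least one summary-statistics table")
    long = pd.concat(
        [t[["variant_id", "beta", "se"]] for t in stats_tables],
        keys=range(len(stats_tables)),
        names=["node"],
    ).reset_index(level="node")
    order = long["variant_id"].drop_duplicates().to_numpy()
    rows = []
    grouped = long.groupby("variant_id", sort=False)
    for vid in order:
        grp = grouped.get_group(vid)
        b = grp["beta"].to_numpy(dtype=np.float64)
        se = grp["se"].to_numpy(dtype=np.float64)
        ok = np.isfinite(b) & np.isfinite(se) & (se > 0)
        b, se = b[ok], se[ok]
        k = len(b)
        if k == 0:
            continue
        w = 1.0 / se**2
        sw = w.sum()
        b_fe = float((w * b).sum() / sw)
        if k == 1:
            tau2 = 0.0
        else:
            q = float((w * (b - b_fe) ** 2).sum())
            denom = sw - float((w**2).sum()) / sw
            tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        w_re = 1.0 / (se**2 + tau2)
        beta_re = float((w_re * b).sum() / w_re.sum())
        se_re = float(1.0 / np.sqrt(w_re.sum()))
        z = beta_re / se_re if se_re > 0 else 0.0
        p = float(np.clip(2.0 * stats.norm.sf(abs(z)), _P_FLOOR, 1.0))
        rows.append((vid, beta_re, se_re, p, tau2, k))
    return pd.DataFrame(rows, columns=["variant_id", "beta", "se", "p", "tau2", "k"])


def select_top_snps(meta: pd.DataFrame, m: int) -> list[str]:
    """The ``m`` most significant variant ids.

    Smallest p first; ties broken by larger \\|pooled beta\\|, then by the
    table (catalog) order. Requesting more variants than available returns
    all of them with a warning.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > len(meta):
        warnings.warn(
            f"requested {m} variants but only {len(meta)} available; returning all"
        )
        m = len(meta)
    df = meta.reset_index(drop=True)
    order = np.lexsort(
        (np.arange(len(df)), -df["beta"].abs().to_numpy(), df["p"].to_numpy())
    )
    return df["variant_id"].to_numpy()[order[:m]].tolist()
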