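"""Per-node genotype quality control, relatedness filtering, LD pruning and
the cross-node variant-union step.

Two QC orders are supported, matching the two study flows: the biobank-style
flow runs sample QC (missingness, then relatedness) before variant QC; the
reference-panel flow runs variant QC first. Both are selectable via
``RunConfig.qc_order``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MISSING, GenotypeBlock

__all__ = [
    "QCThresholds",
    "QCReport",
    "hwe_test",
    "variant_qc",
    "king_kinship",
    "king_kinship_matrix",
    "sample_qc",
    "run_qc",
    "ld_prune",
    "variant_union",
]


@dataclass
class QCThresholds:
    """Filtering thresholds.

    Defaults: 6% sample missingness, kinship 0.0884 (second-degree
    relatives), 5% minimum MAF, 2% variant missingness, HWE p-value 1e-6.
    """

    sample_missingness_max: float = 0.06
    kinship_cutoff: float = 0.0884
    maf_min: float = 0.05
    variant_missingness_max: float = 0.02
    hwe_p_min: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("sample_missingness_max", "maf_min", "variant_missingness_max"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.maf_min > 0.5:
            raise ValueError("maf_min cannot exceed 0.5")


@dataclass
class QCReport:
    """Per-variant and per-sample filter outcomes plus before/after counts.

    ``variants``/``samples`` carry a ``kept`` flag and a ``reason`` column
    (empty string when kept); counts reconcile exactly: kept + removed =
    input.
    """

    variants: pd.DataFrame | None = None
    samples: pd.DataFrame | None = None

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for name, table in (("variants", self.variants), ("samples", self.samples)):
            if table is not None:
                out[f"{name}_in"] = len(table)
                out[f"{name}_kept"] = int(table["kept"].sum())
                out[f"{name}_removed"] = int((~table["kept"]).sum())
        return out


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Hardy-Weinberg goodness-of-fit p-value (1-df chi-square).

    Expected genotype counts are (n p^2, 2 n p q, n q^2) under the sample
    allele frequency. A monomorphic variant has nothing to test and returns
    p = 1 by convention.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be nonnegative")
    n = counts.sum()
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    p = (2 * n_AA + n_Aa) / (2.0 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_pvalues(block: GenotypeBlock) -> np.ndarray:
    """Vectorized 1-df HWE p-values over all variants (non-missing calls)."""
    g = block.dosages
    obs = g != MISSING
    n2 = ((g == 2) & obs).sum(axis=0).astype(np.float64)
    n1 = (g == 1).sum(axis=0).astype(np.float64)
    n0 = ((g == 0) & obs).sum(axis=0).astype(np.float64)
    n = n2 + n1 + n0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n2 + n1) / (2 * n)
        q = 1 - p
        exp2, exp1, exp0 = n * p**2, 2 * n * p * q, n * q**2
        chi2 = (
            (n2 - exp2) ** 2 / exp2
            + (n1 - exp1) ** 2 / exp1
            + (n0 - exp0) ** 2 / exp0
        )
    pvals = stats.chi2.sf(chi2, df=1)
    mono = (p <= 0) | (p >= 1) | (n == 0)
    pvals = np.where(mono, 1.0, pvals)
    return pvals


def variant_qc(
    block: GenotypeBlock, t: QCThresholds | None = None
) -> tuple[GenotypeBlock, QCReport]:
    """Remove variants failing missingness, MAF or HWE thresholds.

    MAF and the HWE test use non-missing calls only. The recorded removal
    reason is the first failing check in the order missingness, maf, hwe.
    """
    t = t or QCThresholds()
    freq = block.allele_frequency()
    maf = np.where(np.isnan(freq), 0.0, np.minimum(freq, 1 - freq))
    _, vmiss = block.missingness()
    hwe_p = _hwe_pvalues(block)
    reasons = np.full(block.n_variants, "", dtype=object)
    fail_miss = vmiss > t.variant_missingness_max
    fail_maf = (maf < t.maf_min) & ~fail_miss
    fail_hwe = (hwe_p < t.hwe_p_min) & ~fail_miss & ~fail_maf
    reasons[fail_miss] = "missingness"
    reasons[fail_maf] = "maf"
    reasons[fail_hwe] = "hwe"
    kept = reasons == ""
    report = QCReport(
        variants=pd.DataFrame(
            {
                "variant_id": block.variant_ids,
                "maf": maf,
                "missingness": vmiss,
                "hwe_p": hwe_p,
                "kept": kept,
                "reason": reasons,
            }
        )
    )
    return block.take_variants(np.flatnonzero(kept)), report


def king_kinship(g_i: np.ndarray, g_j: np.ndarray) -> float:
    """KING-robust between-family kinship estimate for one sample pair.

    phi = (N_AaAa - 2 N_AA,aa) / (N_Aa(i) + N_Aa(j)) over pairwise-complete
    sites. Returns NaN when neither sample has a heterozygous call among the
    complete sites (the estimator is undefined).
    """
    g_i = np.asarray(g_i)
    g_j = np.asarray(g_j)
    if g_i.shape != g_j.shape:
        raise ValueError("genotype vectors must have equal length")
    ok = (g_i != MISSING) & (g_j != MISSING)
    a, b = g_i[ok], g_j[ok]
    n_het_het = int(np.sum((a == 1) & (b == 1)))
    n_opp_hom = int(np.sum(((a == 0) & (b == 2)) | ((a == 2) & (b == 0))))
    denom = int(np.sum(a == 1)) + int(np.sum(b == 1))
    if denom == 0:
        return float("nan")
    return (n_het_het - 2.0 * n_opp_hom) / denom


def king_kinship_matrix(block: GenotypeBlock) -> np.ndarray:
    """All-pairs KING-robust kinship (NaN where undefined); symmetric."""
    g = block.dosages
    obs = (g != MISSING).astype(np.float64)
    het = (g == 1).astype(np.float64)
    hom0 = ((g == 0) & (g != MISSING)).astype(np.float64)
    hom2 = (g == 2).astype(np.float64)
    n_het_het = het @ het.T
    n_opp = hom0 @ hom2.T + hom2 @ hom0.T
    het_in_pair = het @ obs.T  # [i, j] = het sites of i complete in j
    denom = het_in_pair + het_in_pair.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (n_het_het - 2.0 * n_opp) / denom
    phi[denom == 0] = np.nan
    return phi


def sample_qc(
    block: GenotypeBlock, t: QCThresholds | None = None
) -> tuple[GenotypeBlock, QCReport]:
    """Remove high-missingness samples, then greedily resolve related pairs.

    For every pair with kinship >= cutoff, the member with the higher
    missingness is dropped (tie broken toward the later sample in file
    order); one pass over flagged pairs leaves no related pair intact.
    """
    t = t or QCThresholds()
    smiss, _ = block.missingness()
    reasons = np.full(block.n_samples, "", dtype=object)
    reasons[smiss > t.sample_missingness_max] = "missingness"
    alive = np.flatnonzero(reasons == "")
    if len(alive) > 1:
        phi = king_kinship_matrix(block.take_samples(alive))
        with np.errstate(invalid="ignore"):
            related = np.triu(phi >= t.kinship_cutoff, k=1)
        removed_local: set[int] = set()
        for i, j in zip(*np.nonzero(related)):
            if i in removed_local or j in removed_local:
                continue
            gi, gj = alive[i], alive[j]
            # drop the higher-missingness member; tie -> later sample order
            drop = j if (smiss[gj] >= smiss[gi]) else i
            removed_local.add(drop)
            reasons[alive[drop]] = "kinship"
    kept = reasons == ""
    report = QCReport(
        samples=pd.DataFrame(
            {
                "sample_id": block.samples["sample_id"].to_numpy(),
                "missingness": smiss,
                "kept": kept,
                "reason": reasons,
            }
        )
    )
    return block.take_samples(np.flatnonzero(kept)), report


def run_qc(
    block: GenotypeBlock, t: QCThresholds | None = None, order: str = "samples_first"
) -> tuple[GenotypeBlock, QCReport]:
    """Full per-node QC in the configured order."""
    t = t or QCThresholds()
    if order == "samples_first":
        block, rep_s = sample_qc(block, t)
        block, rep_v = variant_qc(block, t)
    elif order == "variants_first":
        block, rep_v = variant_qc(block, t)
        block, rep_s = sample_qc(block, t)
    else:
        raise ValueError("order must be 'samples_first' or 'variants_first'")
    return block, QCReport(variants=rep_v.variants, samples=rep_s.samples)


def ld_prune(
    block: GenotypeBlock, window: int = 50, step: int = 5, r2_max: float = 0.1
) -> list[str]:
    """Sliding-window LD pruning; returns kept variant ids in file order.

    Within each window of ``window`` variants (advancing by ``step``), while
    any surviving pair has squared Pearson correlation above ``r2_max`` (on
    mean-imputed dosages), the currently worst pair is resolved by removing
    its lower-MAF member (tie broken toward the later variant in file order).
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if not 0 < r2_max <= 1:
        raise ValueError("r2_max must lie in (0, 1]")
    x = block.dosages_float(impute="mean")
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    freq = block.allele_frequency()
    maf = np.where(np.isnan(freq), 0.0, np.minimum(freq, 1 - freq))
    m = block.n_variants
    kept = np.ones(m, dtype=bool)
    for start in range(0, max(m - 1, 1), step):
        idx = np.flatnonzero(kept[start : start + window]) + start
        idx = idx[sd[idx] > 0]
        if len(idx) < 2:
            continue
        xs = x[:, idx] / sd[idx]
        r2 = (xs.T @ xs / xs.shape[0]) ** 2
        np.fill_diagonal(r2, 0.0)
        alive = np.ones(len(idx), dtype=bool)
        while True:
            sub = np.where(np.outer(alive, alive), r2, 0.0)
            i, j = np.unravel_index(np.argmax(sub), sub.shape)
            if sub[i, j] <= r2_max:
                break
            # drop the lower-MAF member; tie -> later file order
            gi, gj = idx[i], idx[j]
            drop = j if (maf[gj] <= maf[gi]) else i
            alive[drop] = False
            kept[idx[drop]] = False
    return [vid for vid, k in zip(block.variant_ids, kept) if k]


def variant_union(
    kept_lists: list[list[str]], catalog: list[str] | np.ndarray | None = None
) -> list[str]:
    """Union of per-node kept-variant lists, in global catalog order.

    With no catalog given, ids are ordered by first appearance across the
    concatenated node lists (still deterministic).
    """
    if not kept_lists:
        raise ValueError("need at least one node list")
    members = set().union(*map(set, kept_lists))
    if catalog is None:
        ordered: list[str] = []
        seen: set[str] = set()
        for lst in kept_lists:
            for vid in lst:
                if vid not in seen:
                    seen.add(vid)
                    ordered.append(vid)
        return ordered
    return [vid for vid in catalog if vid in members]
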