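"""Core in-memory containers shared across the pipeline.

Genotypes are stored as minor-allele dosages in ``{0, 1, 2}`` with ``-1``
marking a missing call, packed into an ``int8`` samples x variants matrix.
Variant and sample metadata travel with the matrix as pandas DataFrames whose
row order *is* the authoritative ordering; no operation reorders silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

#: columns of the variant metadata table (PLINK .bim order)
VARIANT_COLUMNS = ["chrom", "variant_id", "cm", "pos", "allele1", "allele2"]


def default_variant_table(n_variants: int, chrom: str = "1") -> pd.DataFrame:
    """Minimal variant metadata for simulated data: ids ``var0001`` ... and
    unit-spaced positions on one chromosome."""
    width = max(4, len(str(n_variants)))
    return pd.DataFrame(
        {
            "chrom": chrom,
            "variant_id": [f"var{i:0{width}d}" for i in range(n_variants)],
            "cm": 0.0,
            "pos": np.arange(1, n_variants + 1, dtype=np.int64),
            "allele1": "A",
            "allele2": "B",
        }
    )


@dataclass
class GenotypeBlock:
    """Samples x variants matrix of minor-allele dosages with metadata.

    Parameters
    ----------
    dosages : int8 array, shape (n_samples, n_variants)
        Minor-allele counts in {0, 1, 2}; -1 encodes a missing call.
    variants : DataFrame
        One row per variant with columns ``chrom, variant_id, cm, pos,
        allele1, allele2``.
    samples : DataFrame
        One row per sample; must contain ``sample_id``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if len(self.variants) != self.dosages.shape[1]:
            raise ValueError("variant table length does not match dosage columns")
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError("sample table length does not match dosage rows")
        bad = ~np.isin(self.dosages, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must lie in {0,1,2} or -1 for missing")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["variant_id"].to_numpy()

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def dosages_float(self, impute: np.ndarray | str | None = "mean") -> np.ndarray:
        """Dosages as float64 with missing entries imputed.

        ``impute`` may be ``"mean"`` (per-variant mean of observed calls),
        a length-``n_variants`` vector of fill values, or ``None`` to leave
        missing entries as NaN.
        """
        x = self.dosages.astype(np.float64)
        miss = self.dosages == MISSING
        x[miss] = np.nan
        if impute is None:
            return x
        if isinstance(impute, str):
            if impute != "mean":
                raise ValueError(f"unknown imputation mode {impute!r}")
            with np.errstate(invalid="ignore"):
                fill = np.nanmean(x, axis=0)
            fill = np.where(np.isnan(fill), 0.0, fill)
        else:
            fill = np.asarray(impute, dtype=np.float64)
            if fill.shape != (self.n_variants,):
                raise ValueError("impute vector length must equal n_variants")
        idx = np.where(miss)
        x[idx] = fill[idx[1]]
        return x

    def allele_frequency(self) -> np.ndarray:
        """Per-variant frequency of allele1 among non-missing calls (NaN if
        a variant has no observed calls)."""
        obs = self.dosages != MISSING
        counts = np.where(obs, self.dosages, 0).sum(axis=0, dtype=np.int64)
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, counts / (2.0 * n_obs), np.nan)

    def missingness(self) -> tuple[np.ndarray, np.ndarray]:
        """(per-sample, per-variant) missing-call fractions."""
        miss = self.dosages == MISSING
        return miss.mean(axis=1), miss.mean(axis=0)

    def take_variants(self, index: np.ndarray) -> "GenotypeBlock":
        index = np.asarray(index)
        return GenotypeBlock(
            self.dosages[:, index],
            self.variants.iloc[index].reset_index(drop=True),
            self.samples.copy(),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeBlock":
        index = np.asarray(index)
        return GenotypeBlock(
            self.dosages[index],
            self.variants.copy(),
            self.samples.iloc[index].reset_index(drop=True),
        )

    def subset_by_variant_id(self, ids: list[str] | np.ndarray) -> "GenotypeBlock":
        """Restrict to the given variant ids, in the given order."""
        pos = pd.Index(self.variants["variant_id"])
        index = pos.get_indexer(list(ids))
        if (index < 0).any():
            missing_ids = np.asarray(list(ids))[index < 0]
            raise KeyError(f"variant ids not in block: {missing_ids[:5]!r} ...")
        return self.take_variants(index)


@dataclass
class NodeDataset:
    """One client's data: genotypes plus per-sample phenotype/covariate table.

    ``phenotypes`` is indexed like ``block.samples`` (same order) and carries
    at least ``sample_id, population, superpopulation``; after phenotype
    simulation also ``age, sex, phenotype``. ``folds`` holds the CV fold index
    per sample (-1 until assigned).
    """

    node_id: str
    block: GenotypeBlock
    phenotypes: pd.DataFrame
    folds: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.folds is None:
            self.folds = np.full(self.block.n_samples, -1, dtype=np.int64)
        self.folds = np.asarray(self.folds, dtype=np.int64)
        if len(self.phenotypes) != self.block.n_samples:
            raise ValueError("phenotype table length does not match samples")
        if self.folds.shape != (self.block.n_samples,):
            raise ValueError("folds length does not match samples")

    @property
    def n_samples(self) -> int:
        return self.block.n_samples

    def with_block(self, block: GenotypeBlock, sample_index: np.ndarray | None = None) -> "NodeDataset":
        """Replace the genotype block, subsetting the phenotype table and fold
        vector when ``sample_index`` says which rows survived."""
        if sample_index is None:
            return replace(self, block=block)
        sample_index = np.asarray(sample_index)
        return NodeDataset(
            self.node_id,
            block,
            self.phenotypes.iloc[sample_index].reset_index(drop=True),
            self.folds[sample_index],
        )
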