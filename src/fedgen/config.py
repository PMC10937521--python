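"""Run configuration: documented defaults, YAML loading, validation.

The defaults are the pipeline's reference settings: QC at 6% sample
missingness, KING kinship cutoff 0.0884 (second-degree relatives), 5% MAF,
2% variant missingness and an HWE p-value floor of 1e-6; 10,000 top SNPs and
20 PCs; LASSO trained with batch 16, learning rate 5e-3, per-epoch decay
0.99, 256 total epochs and 8 epochs per communication round; the MLP with
batch 64, learning rate 0.1, decay 0.9999, 16,384 total epochs and
epochs-per-round swept over {1, 2, 4, 8, 16, 32}.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

log = logging.getLogger("fedgen")

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    experiment: str = "phenotype"  # or "ancestry"
    seed: int = 0
    out_dir: str = "results"

    # quality control
    sample_missingness_max: float = 0.06
    kinship_cutoff: float = 0.0884
    maf_min: float = 0.05
    variant_missingness_max: float = 0.02
    hwe_p_min: float = 1e-6
    qc_order: str = "samples_first"  # or "variants_first"

    # LD pruning
    prune_window: int = 50
    prune_step: int = 5
    prune_r2_max: float = 0.1

    # feature selection / GWAS
    top_snps: int = 10000
    gwas_pcs: int = 20

    # PCA
    n_pcs: int = 20
    pca_standardize: bool = False

    # LASSO bank
    lasso_batch_size: int = 16
    lasso_lr: float = 5e-3
    lasso_decay: float = 0.99
    lasso_total_epochs: int = 256
    lasso_epochs_per_round: int = 8
    lasso_n_lambda: int = 32

    # MLP classifier
    mlp_hidden: tuple[int, int] = (800, 200)
    mlp_batch_size: int = 64
    mlp_lr: float = 0.1
    mlp_decay: float = 0.9999
    mlp_total_epochs: int = 16384
    mlp_epochs_per_round_sweep: tuple[int, ...] = (1, 2, 4, 8, 16, 32)

    # cross-validation
    n_folds: int = 10

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.experiment not in ("phenotype", "ancestry"):
            raise ValueError("experiment: must be 'phenotype' or 'ancestry'")
        for key in ("sample_missingness_max", "variant_missingness_max", "maf_min"):
            v = getattr(self, key)
            if not 0 <= v <= 1:
                raise ValueError(f"{key}: {v} outside [0, 1]")
        if self.maf_min > 0.5:
            raise ValueError(f"maf_min: {self.maf_min} exceeds 0.5 (MAF is at most 0.5)")
        if not 0 < self.hwe_p_min <= 1:
            raise ValueError(f"hwe_p_min: {self.hwe_p_min} outside (0, 1]")
        if self.qc_order not in ("samples_first", "variants_first"):
            raise ValueError("qc_order: must be 'samples_first' or 'variants_first'")
        if self.prune_window < 2:
            raise ValueError(f"prune_window: {self.prune_window} must be >= 2")
        if not 0 < self.prune_r2_max <= 1:
            raise ValueError(f"prune_r2_max: {self.prune_r2_max} outside (0, 1]")
        for key in (
            "top_snps", "n_pcs", "lasso_total_epochs", "lasso_epochs_per_round",
            "mlp_total_epochs", "lasso_n_lambda", "lasso_batch_size",
            "mlp_batch_size", "n_folds",
        ):
            if getattr(self, key) < 1:
                raise ValueError(f"{key}: must be >= 1")
        if self.gwas_pcs < 0:
            raise ValueError("gwas_pcs: must be >= 0")
        for key in ("lasso_lr", "mlp_lr"):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key}: must be positive")
        for key in ("lasso_decay", "mlp_decay"):
            if not 0 < getattr(self, key) <= 1:
                raise ValueError(f"{key}: must lie in (0, 1]")


_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; missing keys fall back to the documented defaults.

    Unknown keys and out-of-range values are rejected with the offending key
    named. An empty (or absent) file yields all defaults. The fully resolved
    configuration is echoed to the log.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must be a mapping of keys to values")
        raw = loaded
    unknown = set(raw) - set(_FIELDS)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("mlp_hidden", "mlp_epochs_per_round_sweep"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = RunConfig(**raw)
    for name in _FIELDS:
        log.info("config %s = %r", name, getattr(cfg, name))
    return cfg
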