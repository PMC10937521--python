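"""Multi-node genotype/phenotype/ancestry simulation.

The generator emulates the two federation regimes the pipeline is designed
for without any real cohort:

* a *low-heterogeneity* regime: many nodes drawing from mildly diverged
  populations of shared ancestry, with a quantitative phenotype of additive
  genetic architecture plus age/sex covariates (biobank-split-by-centre
  style);
* a *high-heterogeneity* regime: few nodes, each holding one continental
  superpopulation composed of several nested subpopulations (reference-panel
  style), used for ancestry classification.

Population structure follows the Balding-Nichols model: for a variant with
ancestral frequency ``p`` and a population with divergence ``F`` (an FST
dial), the population frequency is drawn from
``Beta(p(1-F)/F, (1-p)(1-F)/F)``, which has mean ``p`` and variance
``F p (1-p)``. For the nested regime a two-level version is used: superpopulation
frequencies are drawn from the ancestral pool first, subpopulation
frequencies from their superpopulation. Variants are exchangeable (no
linkage-disequilibrium map); correlated variants for pruning tests are
injected explicitly by callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeBlock, NodeDataset, default_variant_table

__all__ = [
    "PopulationModel",
    "TraitModel",
    "NodeSpec",
    "draw_population_frequencies",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_phenotypes",
    "draw_causal_effects",
    "ukb_like_regime",
    "thousand_genomes_like_regime",
]


@dataclass
class PopulationModel:
    """Balding-Nichols population structure.

    Parameters
    ----------
    n_populations : int
        Number of (sub)populations.
    fst : sequence of float
        Per-population divergence from the ancestral pool, each in [0, 1).
        With ``superpop_fst`` set, this is the divergence of a subpopulation
        from its superpopulation.
    ancestral_freq_range : (low, high)
        Ancestral allele frequencies are drawn uniformly on this interval,
        which must lie within (0.01, 0.99).
    n_variants : int
    superpop_assignment : dict
        population index -> superpopulation label. Every population maps to
        exactly one superpopulation.
    superpop_fst : dict or None
        superpopulation label -> divergence of the superpopulation from the
        ancestral pool. When given, frequencies are drawn hierarchically.
    """

    n_populations: int
    fst: np.ndarray
    ancestral_freq_range: tuple[float, float]
    n_variants: int
    superpop_assignment: dict[int, str]
    superpop_fst: dict[str, float] | None = None
    population_names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.fst = np.asarray(self.fst, dtype=np.float64)
        if self.fst.shape == ():
            self.fst = np.full(self.n_populations, float(self.fst))
        if self.fst.shape != (self.n_populations,):
            raise ValueError("fst must give one value per population")
        if np.any(self.fst < 0) or np.any(self.fst >= 1):
            raise ValueError("fst values must lie in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0.01 < lo < hi < 0.99):
            raise ValueError("ancestral_freq_range must lie within (0.01, 0.99)")
        if set(self.superpop_assignment) != set(range(self.n_populations)):
            raise ValueError("superpop_assignment must map every population index")
        if self.superpop_fst is not None:
            missing = set(self.superpop_assignment.values()) - set(self.superpop_fst)
            if missing:
                raise ValueError(f"superpop_fst missing labels: {missing}")
            for v in self.superpop_fst.values():
                if not 0 <= v < 1:
                    raise ValueError("superpop fst values must lie in [0, 1)")
        if self.population_names is None:
            self.population_names = [f"POP{k:02d}" for k in range(self.n_populations)]


@dataclass
class TraitModel:
    """Additive quantitative trait.

    ``heritability`` is the target share of phenotypic variance explained by
    the true genetic score; the residual noise variance is derived from it
    (see :func:`simulate_phenotypes`). ``noise_sd`` may be set to bypass the
    heritability calibration with a fixed residual scale.
    """

    n_causal: int
    heritability: float
    covariate_effects: tuple[float, float] = (0.01, 0.25)  # (age per year, sex)
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.heritability <= 1:
            raise ValueError("heritability must lie in [0, 1]")
        if self.n_causal < 0:
            raise ValueError("n_causal must be nonnegative")


@dataclass
class NodeSpec:
    """One client node: a sample count and a mixture over populations."""

    node_id: str
    n_samples: int
    population_mixture: np.ndarray

    def __post_init__(self) -> None:
        self.population_mixture = np.asarray(self.population_mixture, dtype=np.float64)
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if np.any(self.population_mixture < 0):
            raise ValueError("mixture weights must be nonnegative")
        if abs(self.population_mixture.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")


def _balding_nichols(rng: np.random.Generator, base: np.ndarray, f: float) -> np.ndarray:
    """Draw diverged frequencies around ``base`` at divergence ``f``."""
    if f == 0.0:
        return base.copy()
    a = base * (1.0 - f) / f
    b = (1.0 - base) * (1.0 - f) / f
    return rng.beta(a, b)


def draw_population_frequencies(model: PopulationModel, seed: int) -> np.ndarray:
    """Per-population allele-frequency matrix, shape (n_populations, n_variants).

    Deterministic given ``seed``. Populations with ``F = 0`` return the
    ancestral frequencies exactly.
    """
    rng = np.random.default_rng(seed)
    lo, hi = model.ancestral_freq_range
    ancestral = rng.uniform(lo, hi, size=model.n_variants)
    if model.superpop_fst is None:
        return np.vstack(
            [_balding_nichols(rng, ancestral, f) for f in model.fst]
        )
    super_freq: dict[str, np.ndarray] = {}
    for label in sorted(set(model.superpop_assignment.values())):
        super_freq[label] = _balding_nichols(rng, ancestral, model.superpop_fst[label])
    rows = []
    for k in range(model.n_populations):
        base = super_freq[model.superpop_assignment[k]]
        rows.append(_balding_nichols(rng, base, model.fst[k]))
    return np.vstack(rows)


def simulate_genotypes(
    freqs: np.ndarray,
    specs: list[NodeSpec],
    missing_rate: float,
    seed: int,
    model: PopulationModel | None = None,
) -> list[NodeDataset]:
    """Draw per-node genotype blocks from population frequencies.

    Each sample's population is drawn from its node's mixture, dosages are
    Binomial(2, population frequency) per variant, and calls are masked
    missing independently at ``missing_rate``. Population (and, when a
    :class:`PopulationModel` is supplied, superpopulation) labels are
    recorded per sample.
    """
    if not specs:
        raise ValueError("need at least one NodeSpec")
    if not 0 <= missing_rate <= 0.2:
        raise ValueError("missing_rate must lie in [0, 0.2]")
    freqs = np.asarray(freqs, dtype=np.float64)
    n_pops, n_variants = freqs.shape
    pop_names = (
        model.population_names if model is not None else [f"POP{k:02d}" for k in range(n_pops)]
    )
    rng = np.random.default_rng(seed)
    nodes = []
    for spec in specs:
        if spec.population_mixture.shape != (n_pops,):
            raise ValueError("mixture length must equal number of populations")
        pops = rng.choice(n_pops, size=spec.n_samples, p=spec.population_mixture)
        dosages = rng.binomial(2, freqs[pops]).astype(np.int8)
        if missing_rate > 0:
            mask = rng.random(dosages.shape) < missing_rate
            dosages[mask] = MISSING
        sample_ids = [f"{spec.node_id}_s{i:05d}" for i in range(spec.n_samples)]
        superpops = (
            [model.superpop_assignment[int(p)] for p in pops]
            if model is not None
            else ["NA"] * spec.n_samples
        )
        samples = pd.DataFrame({"sample_id": sample_ids})
        phen = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "node_id": spec.node_id,
                "population": [pop_names[int(p)] for p in pops],
                "population_index": pops.astype(np.int64),
                "superpopulation": superpops,
            }
        )
        block = GenotypeBlock(dosages, default_variant_table(n_variants), samples)
        nodes.append(NodeDataset(spec.node_id, block, phen))
    return nodes


def draw_causal_effects(
    n_variants: int, n_causal: int, seed: int, scale: float | None = None
) -> np.ndarray:
    """Sparse effect-size vector: ``n_causal`` variants chosen uniformly,
    effects ~ N(0, scale^2) with scale defaulting to 1/sqrt(n_causal) so the
    genetic-score variance is O(1) regardless of polygenicity."""
    if n_causal > n_variants:
        raise ValueError("n_causal cannot exceed n_variants")
    rng = np.random.default_rng(seed)
    effects = np.zeros(n_variants)
    if n_causal == 0:
        return effects
    idx = rng.choice(n_variants, size=n_causal, replace=False)
    if scale is None:
        scale = 1.0 / np.sqrt(n_causal)
    effects[idx] = rng.normal(0.0, scale, size=n_causal)
    return effects


_AGE_VAR = (31.0**2 - 1.0) / 12.0  # discrete uniform on [40, 70]
_SEX_VAR = 0.25


def _genetic_score(node: NodeDataset, causal_effects: np.ndarray) -> np.ndarray:
    x = node.block.dosages_float(impute="mean")
    return x @ np.asarray(causal_effects, dtype=np.float64)


def simulate_phenotype(
    node: NodeDataset,
    trait: TraitModel,
    causal_effects: np.ndarray,
    seed: int,
    noise_sd: float | None = None,
) -> NodeDataset:
    """Attach ``age``, ``sex`` and ``phenotype`` columns to one node.

    ``y = genetic score + covariate effects . (age, sex) + N(0, noise_sd^2)``
    with age ~ discrete uniform [40, 70] and sex ~ Bernoulli(0.5). Missing
    dosages are mean-imputed in the genetic score. When ``noise_sd`` is not
    supplied (directly or on the trait), it is derived from the trait
    heritability using this node's empirical genetic-score variance; for a
    multi-node study use :func:`simulate_phenotypes`, which calibrates one
    shared noise scale from the pooled score variance.
    """
    rng = np.random.default_rng(seed)
    g = _genetic_score(node, causal_effects)
    h2 = trait.heritability
    var_g = float(np.var(g))
    if noise_sd is None:
        noise_sd = trait.noise_sd
    if noise_sd is None:
        noise_sd = _noise_sd_for(trait, var_g)
    if h2 == 0.0:
        g = np.zeros_like(g)
    age = rng.integers(40, 71, size=node.n_samples).astype(np.float64)
    sex = rng.integers(0, 2, size=node.n_samples).astype(np.float64)
    b_age, b_sex = trait.covariate_effects
    y = g + b_age * age + b_sex * sex + rng.normal(0.0, noise_sd, size=node.n_samples)
    phen = node.phenotypes.copy()
    phen["age"] = age
    phen["sex"] = sex
    phen["phenotype"] = y
    return NodeDataset(node.node_id, node.block, phen, node.folds.copy())


def _noise_sd_for(trait: TraitModel, var_g: float) -> float:
    h2 = trait.heritability
    b_age, b_sex = trait.covariate_effects
    var_cov = b_age**2 * _AGE_VAR + b_sex**2 * _SEX_VAR
    if h2 == 0.0:
        # genetic score is dropped; any residual scale is valid, keep O(1)
        return 1.0
    if var_g <= 0.0:
        raise ValueError("nonzero heritability requires a nonzero genetic score")
    if h2 == 1.0:
        if var_cov > 0:
            raise ValueError("heritability 1 is incompatible with covariate effects")
        return 0.0
    var_e = var_g * (1.0 - h2) / h2 - var_cov
    if var_e < 0:
        raise ValueError(
            "covariate effects too large for the requested heritability"
        )
    return float(np.sqrt(var_e))


def simulate_phenotypes(
    nodes: list[NodeDataset],
    trait: TraitModel,
    causal_effects: np.ndarray,
    seed: int,
) -> list[NodeDataset]:
    """Simulate the phenotype on every node under one shared true model.

    The residual noise scale is calibrated once from the pooled empirical
    genetic-score variance so Var(genetic)/Var(y) approaches the trait
    heritability on large samples, identically on all nodes.
    """
    g_all = np.concatenate([_genetic_score(n, causal_effects) for n in nodes])
    noise_sd = trait.noise_sd
    if noise_sd is None:
        noise_sd = _noise_sd_for(trait, float(np.var(g_all)))
    return [
        simulate_phenotype(node, trait, causal_effects, seed + 1000 * i, noise_sd=noise_sd)
        for i, node in enumerate(nodes)
    ]


# ---------------------------------------------------------------------------
# Study regimes


def ukb_like_regime(
    n_nodes: int = 19,
    samples_per_node: int = 2000,
    n_variants: int = 5000,
    fst_range: tuple[float, float] = (0.001, 0.01),
) -> tuple[PopulationModel, list[NodeSpec]]:
    """Many-node, low-heterogeneity regime: one mildly diverged population
    per node, all sharing ancestry (one superpopulation)."""
    fst = np.linspace(fst_range[0], fst_range[1], n_nodes)
    model = PopulationModel(
        n_populations=n_nodes,
        fst=fst,
        # keep ancestral MAF clear of the 5% QC cutoff so the candidate set
        # survives per-node filtering on every node
        ancestral_freq_range=(0.1, 0.9),
        n_variants=n_variants,
        superpop_assignment={k: "EUR" for k in range(n_nodes)},
    )
    specs = []
    for k in range(n_nodes):
        mixture = np.zeros(n_nodes)
        mixture[k] = 1.0
        specs.append(NodeSpec(f"node{k:02d}", samples_per_node, mixture))
    return model, specs


#: superpopulation -> number of nested subpopulations (26 in total)
_TGP_SUPERPOPS = {"AFR": 7, "AMR": 4, "EAS": 5, "EUR": 5, "SAS": 5}


def thousand_genomes_like_regime(
    samples_per_node: tuple[int, ...] | int = (660, 510, 570, 600, 640),
    n_variants: int = 2000,
    subpop_fst: tuple[float, float] = (0.05, 0.15),
    superpop_fst: float = 0.12,
) -> tuple[PopulationModel, list[NodeSpec]]:
    """Few-node, high-heterogeneity regime: 5 nodes holding disjoint
    superpopulations with 26 subpopulation labels nested inside them."""
    labels = sorted(_TGP_SUPERPOPS)
    if isinstance(samples_per_node, int):
        samples_per_node = (samples_per_node,) * len(labels)
    if len(samples_per_node) != len(labels):
        raise ValueError("need one sample count per superpopulation node")
    assignment: dict[int, str] = {}
    names: list[str] = []
    k = 0
    for label in labels:
        for j in range(_TGP_SUPERPOPS[label]):
            assignment[k] = label
            names.append(f"{label}{j}")
            k += 1
    n_pops = k
    rng = np.random.default_rng(2024)  # fixed regime definition, not a data seed
    fst = rng.uniform(subpop_fst[0], subpop_fst[1], size=n_pops)
    model = PopulationModel(
        n_populations=n_pops,
        fst=fst,
        ancestral_freq_range=(0.05, 0.95),
        n_variants=n_variants,
        superpop_assignment=assignment,
        superpop_fst={label: superpop_fst for label in labels},
        population_names=names,
    )
    specs = []
    for label, n_samples in zip(labels, samples_per_node):
        mixture = np.array(
            [1.0 if assignment[i] == label else 0.0 for i in range(n_pops)]
        )
        mixture /= mixture.sum()
        specs.append(NodeSpec(label, int(n_samples), mixture))
    return model, specs
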