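# Methods

`fedgen` simulates cross-silo federated learning on genotype data entirely
in-process: a set of client nodes with private genotype/phenotype data, a
server that only ever sees model parameters, per-variant summary statistics,
variant-id lists, or PCA packets, and a harness that compares local,
federated and centralized versions of the same model on identical test data.
This note records the models, the defaults and the design choices that were
genuinely open.

## Synthetic cohorts

Population structure follows the Balding–Nichols model: a variant's
ancestral frequency `p` is drawn uniformly from a configured interval, and a
population with divergence `F` (an FST dial in `[0, 1)`) draws its frequency
from `Beta(p(1−F)/F, (1−p)(1−F)/F)` (mean `p`, variance `F·p(1−p)`;
`F = 0` returns `p` exactly). Genotypes are `Binomial(2, frequency)`
minor-allele dosages with missing calls masked completely at random.
Variants are exchangeable — there is no linkage-disequilibrium map; LD
pruning is exercised by injecting duplicated/correlated variants in tests.

Two regimes mirror the study designs:

* **Low heterogeneity** (`ukb_like_regime`): 19 nodes, one mildly diverged
  population each (`F` linearly spaced over `[0.001, 0.01]`), shared
  ancestry, ancestral frequencies on `(0.1, 0.9)` so a 5 % MAF filter trims
  genuine outliers rather than the bulk. A quantitative phenotype
  `y = X·β + β_age·age + β_sex·sex + ε` uses a sparse effect vector
  (`n_causal` variants, effects `N(0, 1/n_causal)`), `age ~ U{40..70}`,
  `sex ~ Bernoulli(0.5)`, small covariate effects `(0.01/year, 0.25)`, and a
  residual scale calibrated once from the pooled empirical genetic-score
  variance so that `Var(genetic)/Var(y)` meets the target heritability
  identically on all nodes. Heritability is a free parameter (default 0.5 in
  the experiment configs).
* **High heterogeneity** (`thousand_genomes_like_regime`): 5 nodes holding
  disjoint continental superpopulations (AFR, AMR, EAS, EUR, SAS) with 26
  subpopulation labels nested inside them (7/4/5/5/5). Frequencies are drawn
  hierarchically: superpopulation from the ancestral pool at `F = 0.12`,
  subpopulations from their superpopulation at per-population `F` in
  `[0.05, 0.15]`. A flat (single-level) draw would produce 26 equidistant
  clusters and no superpopulation signal, which is not what continental
  ancestry looks like; the two-level model restores the nesting the
  experiments rely on.

## Quality control

Per-node thresholds: sample missingness ≤ 6 %, KING-robust kinship
< 0.0884 (second-degree relatives), MAF ≥ 5 %, variant missingness ≤ 2 %,
HWE p ≥ 1e−6. HWE uses the closed-form 1-df chi-square goodness-of-fit test
(not the exact test), adequate at simulated counts; monomorphic variants
return p = 1 by convention. KING-robust:
`φ̂ = (N_Aa,Aa − 2·N_AA,aa) / (N_Aa(i) + N_Aa(j))` over pairwise-complete
sites, undefined (NaN) when neither sample has a heterozygous call.
Relatedness removal is greedy: one pass over flagged pairs, dropping the
higher-missingness member (tie → later file order). Two QC orders are
config-selectable: samples-then-variants (biobank flow) and
variants-then-samples (reference-panel flow).

The KING estimator needs enough markers to be usable at the 0.0884 cutoff:
its null spread is ≈ `0.9/√m`, so below ~2,000 variants unrelated pairs
start crossing the second-degree threshold. The experiment configs therefore
simulate 2,000 variants even though the downstream models use far fewer.

LD pruning slides a window of 50 variants in steps of 5; while any surviving
within-window pair exceeds `r² = 0.1` (Pearson on mean-imputed dosages), the
currently worst pair loses its lower-MAF member (tie → later file order).
The cross-node variant union communicates only variant ids.

## GWAS and meta-analysis

Each node fits per-variant OLS of the phenotype on (dosage, age, sex, 20
within-node genotype PCs, intercept) on training folds only, with
mean-imputed dosages; p-values are two-sided from the t distribution and
floored at the smallest positive double. The server pools per-variant
(β, SE) with DerSimonian–Laird random effects:
`w = 1/SE²`, `Q = Σw(β−β_FE)²`, `τ² = max(0, (Q−(k−1))/(Σw−Σw²/Σw))`,
RE weights `1/(SE²+τ²)`, p from the normal approximation. τ² is floored at
zero, where the pool coincides with fixed effects. Feature selection takes
the `m` smallest p-values (ties → larger |β|, then catalog order); no
genomic control or clumping.

## Federated PCA

Clients eigendecompose their *locally centered* scatter (rank ≤ n_k−1, so
n_k−1 components are the maximum available) after imputing missing calls
with the shared global center (one (sum, count) aggregation round). The
upload is `√λ_i·v_i` rows plus one `√n_k·(μ_k − μ)` mean-offset row per
client; the Gram of the server's stacked matrix then equals the pooled
globally centered scatter *exactly*, so its SVD reproduces centralized PCA
up to floating point whenever the retained spectrum is separated from the
discarded one. Loadings get a deterministic sign (largest-magnitude entry
positive); subspace comparisons use principal angles, never per-vector
equality. Genotypes are not variance-standardized before PCA by default
(`1/√(2p(1−p))` scaling is a flag). Communication is billed as
`Σ_k d_k(m+1)` uploaded values plus `n_pcs·m` broadcast values per client —
linear in the variant count `m`.

## Models

**LASSO bank.** One linear model per penalty on a log-spaced grid of 32
values from `λ_max` down to `10⁻³·λ_max`, where
`λ_max = 2·max_j |x_jᵀ(y−ȳ)|/n` for the loss
`mean((y−Xw−b)²) + λ‖w‖₁` (intercept unpenalized). Training is proximal
SGD: a gradient step on the squared error followed by soft-thresholding at
`η·λ`, which produces exact zeros. Updates run row-by-row over the grid on
shared shuffled batches, so the bank is bit-identical to independently
trained single-λ models — the "parallel" bank is purely an efficiency
device. Features are standardized with training-fold moments (federated:
one (sum, sumsq, count) aggregation); weights start at zero. On a centered
orthonormal design (`XᵀX = nI`) the optimum is `soft(β_OLS, λ/2)`, and
sklearn's coordinate descent at `α = λ/2` is the cross-check. λ selection:
argmin of validation-count-weighted aggregated validation MSE over
(round, λ), ties toward larger λ, then the earlier round.

**MLP ancestry classifier.** Fully connected 20→800→200→26 with selu
activations (published constants), raw-score outputs, cross-entropy loss —
182,226 parameters. LeCun-normal initialization, seeded. Parameters and
activations are float32: the inputs are 20 standardized PC scores and the
metrics sit far above single-precision resolution, while throughput roughly
doubles. PC-score inputs are standardized per component with training-fold
moments; without that, the input scale grows with the variant count behind
the PCA and a 0.1 learning rate can diverge.

**Optimizers.** Plain SGD with multiplicative per-epoch decay (0.99 LASSO,
0.9999 MLP), the decay following a *global* epoch counter across federated
rounds so R rounds × E epochs consume the same learning-rate sequence as
R·E local epochs. Batch sizes 16 (LASSO) and 64 (MLP).

## FedAvg engine

Each round: broadcast → E local epochs of seeded mini-batch SGD per client
(isolated state; "parallel" is a no-leakage contract, not concurrency) →
sample-size-weighted parameter average. All clients participate every round
(cross-silo). The batch generator of client k in round r is seeded from
(seed, k, r), making single-client federation bit-identical to local
training; with identical client data, full batches and E = 1 the round
average equals the pooled gradient step, matching centralized descent to
rounding error. Validation losses are aggregated weighted by client
validation counts; the returned model is the best checkpoint over rounds
(the final-round model is also kept for convergence analyses). Per-round
logs carry client training losses before/after the local fit — the
"before" loss of a freshly received average exceeding the previous "after"
loss is the client-drift spike diagnostic. Communication is billed at one
full parameter set down and up per client per round.

## Experiment harness

10-fold CV per node; iteration t uses fold t as test, fold (t+1) mod 10 as
validation, the rest as training (one concrete reading of the 8/1/1 split).
Everything fold-dependent — GWAS, meta-analysis, λ_max, standardization and
imputation means, PCA centering and loadings — comes from training folds
only; QC and pruning use the full node (they do not see the phenotype or
labels). All models in a comparison are evaluated on the identical merged
test set. Summary intervals are medians with 0.1–0.9 quantiles (linear
interpolation; a drop-the-extremes mode is available).

**Phenotype study.** 19 nodes with sizes cycling (120, 250, 420) — a range
of node sizes on purpose — 2,000 variants, 20 causal, h² = 0.5. Per fold:
per-node GWAS → DL meta → top-50 SNPs (also per-node local and pooled
centralized selections); LASSO banks trained locally per node (both local
and meta feature sets), federated over all nodes (8 epochs/round), and
centralized, 64 total epochs; covariates-only OLS baselines. Candidate
variants are restricted to those passing QC on *every* node so all
selections address one shared space.

**Ancestry study.** 5 superpopulation nodes sized (80, 62, 70, 74, 78),
2,000 variants, per-node pruning → union capped at 300 variants (the
pruning-strictness budget; more markers make the PC space so clean the
schedules stop differing) → exact federated PCA → 20 standardized PCs →
FedAvg MLPs at 512 total epochs for epochs/round in {1, 2, 4, 8, 16, 32},
plus a centralized MLP; communication accounting includes the federated-PCA
bill. The PCA input sweep re-runs federated vs centralized PCA at several
pruning strictnesses under a fixed short-budget centralized classifier.

These sizes are deliberately desk-scale: small enough that both studies run
on a single CPU in minutes, large enough that the qualitative orderings —
every local model below the federated model, federated at or just below
centralized, less-frequent communication converging more slowly under
heterogeneity, aggregation spikes in long local runs — emerge from the
simulated signal rather than being imposed.

## What the simulations do and do not show

The generator reproduces the statistical skeleton the methods operate on:
allele-frequency divergence between silos, nested ancestry, additive
polygenic signal, covariates, missingness and relatedness. It omits LD
structure along the genome, realistic site-frequency spectra, non-additive
effects, genotyping batch effects and phenotype measurement error. Passing
tests therefore demonstrate the correctness and the relative behavior of
the algorithms under controlled structure, not absolute performance on real
cohorts; accuracy figures obtained on real biobank or reference-panel
data are not reproduction targets here.

## Numerical conventions and edge cases

* Dosages are int8 with −1 for missing; imputation is always explicit
  (per-variant means, global PCA center, or training-fold means).
* A phenotype whose covariate-adjusted residual is numerically zero yields
  exact null GWAS results (β = 0, p = 1) rather than rounding noise.
* Monomorphic variants: HWE p = 1, testable-variant filter removes
  zero-variance dosages from GWAS output with a recorded reason.
* Meta-analysis drops non-finite or zero-SE study entries and records `k`.
* PLINK 1 I/O is bit-exact: variant-major only, 2-bit codes with the lowest
  bits holding the first sample, payload length validated.
* All stochastic components draw from `numpy` Generators seeded explicitly;
  experiment sub-stages derive child seeds by fixed offsets, and federated
  batch shuffling uses the documented (seed, client, round) convention.

## Known limitations

Federation is simulated sequentially in one process; there is no real
networking, straggler handling, client sampling or privacy mechanism
(differential privacy, secure aggregation) — parameters are exchanged in
the clear by design, as the point is model behavior, not a deployment.
Binary phenotypes, mixed-model association, exact-test HWE and
LD-aware clumping are out of scope. The KING estimator is reliable only
with a few thousand markers, and the in-memory representation assumes the
cohort fits in RAM.
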