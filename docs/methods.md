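# Methods

## The model

`longkmt` tests a pathway — a set of SNPs grouped into genes, optionally
with a gene-interaction topology — for association with a longitudinal
quantitative phenotype. The observation model is a semiparametric linear
mixed model: for subject *i* with measurements at integer times
*t = 0, …, m−1*,

    y_i = X_i β + h(g_i) + Z_i b_i + ε_i,

with fixed covariates `X_i` (intercept, user covariates, time), a random
intercept and random time slope `b_i ~ N(0, D)` (unstructured 2×2 `D`),
iid residuals `ε_i ~ N(0, σ_ε² I)`, and a genetic term `h` lying in the
RKHS of a kernel `k` over genotype vectors, treated as a random effect
`h ~ N(0, τK)`. The null hypothesis of no pathway effect is `H0: τ = 0`,
tested with the variance-component score statistic

    Q = ½ (y − Xβ̂₀)ᵀ Σ̂₀⁻¹ K Σ̂₀⁻¹ (y − Xβ̂₀),

where `β̂₀, Σ̂₀ = Z D̂ Zᵀ + σ̂_ε² I` come from the null (genetics-free)
REML fit. Under `H0`, `Q ~ Σ_l λ_l χ²₁` with `λ_l` the eigenvalues of
`½ V₀^{1/2} Σ̂₀⁻¹ K Σ̂₀⁻¹ V₀^{1/2}`, `V₀ = Σ̂₀ − X(XᵀΣ̂₀⁻¹X)⁻¹Xᵀ`.
A useful identity: `Σ̂₀⁻¹V₀Σ̂₀⁻¹` equals the residual projection
`P₀ = Σ̂₀⁻¹ − Σ̂₀⁻¹X(XᵀΣ̂₀⁻¹X)⁻¹XᵀΣ̂₀⁻¹` and `P₀Σ̂₀P₀ = P₀`, so with a
kernel factorization `K = BBᵀ` the nonzero `λ_l` are the eigenvalues of
the small matrix `½ BᵀP₀B` — this s×s reduction is the default
computational path, and it is provably identical to the dense formula
(tested to 1e−8).

Three effects can be tested. *Main*: `K` built from genotype rows `g_i`
repeated over observations. *Time interaction*: `K₂` built from rows
`t_ij·g_i`, with the same genetics-free null. *Adjusted interaction*
(used for joint main+interaction alternatives): the top `n_pcs` (default
2) kernel-PCA components of the main kernel are appended to `X` as fixed
effects before testing `K₂`; this avoids refitting a mixed model with a
dense genetic covariance.

For two-time-point pre/post designs an ANCOVA comparator is provided:
OLS of the follow-up measurement on covariates plus baseline, with
`Q_cross = rᵀKr / (2σ̂_ε²)` and mixture weights `½ eig((I−H)K(I−H))`.
The reported `(Q, λ)` pair is internally consistent (the p-value equals
the `Q_long` pairing; both are invariant to rescaling either `K` or the
residual variance).

### Kernels

* linear `K = GGᵀ` — additive SNP contributions;
* quadratic `K_ij = (1 + g_iᵀg_j)²` (offset/degree configurable) — adds
  pairwise dosage interactions;
* network `K = G A N Aᵀ Gᵀ` — `A` the SNP×gene annotation (0/1, or
  `1/√c_g`-scaled columns for the size-adjusted variant), `N` the gene
  adjacency with unit diagonal.  A non-PSD `N` is repaired by the minimal
  diagonal shift `N + (|λ_min|+1e−6)I`, which preserves the topology
  exactly and is flagged in results.  Intuition: `GA` collapses each gene
  to a dosage burden score; `N` then mixes connected genes, so a dense
  pathway mostly adds noise while a sparse one adds specific structure.

Kernel p-values are invariant to positive rescaling of `K`; no trace
normalization is applied by default (a `normalized()` helper exists for
display purposes).

### P-values

The tail of `Σ λ_l χ²₁` is computed by numerical inversion of the
characteristic function (Davies/Imhof family) to ~1e−6 accuracy, with a
Liu-type moment-matching fallback whenever the quadrature fails or
returns a non-positive value (`pvalue_method` reports which route was
used; p is clamped to `(1e−15, 1]`). Eigenvalues below `1e−10·λ_max` are
dropped as quadrature-resolution noise. For the simulation engine the
integrand is evaluated through the determinant identity
`det(I+iuA) = det(I+iu·wD̃)·det(I_p − iu Ũᵀ(I+iu·wD̃)⁻¹Ũ)` with `D̃` a
precomputed Gram eigenbasis and `Ũ` the rank-p fixed-effect downdate, so
no per-replicate eigendecomposition of the 950-SNP matrix is needed; the
phase of the rank-p determinant is unwrapped by continuity along the
integration grid.

### Null-model fitting

REML, with `D` parameterized through its log-Cholesky factor (singular
`D` appears as a boundary fit, retained and flagged). Because every
subject's covariance block depends only on its observed-time pattern,
subjects are grouped by pattern and all per-subject sums collapse into
per-pattern cross-product tensors, making one objective evaluation O(p²m²)
per pattern irrespective of n. The fit agrees with statsmodels MixedLM to
~5 decimals (cross-checked in the test suite) at roughly 1/100 of the
runtime, which is what makes refitting the null tens of thousands of
times in the simulation study feasible. At m=2 the four variance
parameters are not separately identifiable from the three free entries of
a 2×2 marginal covariance; the marginal fit (and hence the test) is still
well defined. Missing records are simply absent rows (MAR); no
imputation. Single-time-point data are refused and directed to the
cross-sectional mode.

## The synthetic data generator

Phenotypes: `y_ij = 0.5·X1_i + 0.25·X2_i + 0.2·t_j + b_{0i} + b_{1i}t_j +
ε_ij` with `X1 ~ Bernoulli(0.5)`, `X2 ~ N(50, 5)` (sd 5),
`Var(b) = [[1, −0.5], [−0.5, 1]]`, `σ_ε² = 1`. Genetic alternatives add
`β·Σ_k SNP_ik` (main), `β·Σ_k SNP_ik·t_j` (interaction) or both (joint)
over 3 causal genes × 3 causal SNPs (the first 3 SNPs of each causal
gene — a deterministic, configurable rule). Missingness keeps every
baseline record and drops later records with probability logistic in
`(X1, (X2−50)/5, t)` (slopes 0.5, 0.3, 0.3), the intercept calibrated by
bisection so the expected missing share of non-baseline records hits the
target; the mechanism never sees the removed `y`, so it is MAR by
construction (verified by a logistic diagnostic in the tests).

Genotypes (default, `genotype_model="haplotype"`): each of the 19
pseudo-genes is an independent neutral-coalescent locus (msprime,
`Ne = 3,100` — the published LD-effective size of European populations —
`μ = 1.25e−8`, `r = 1e−8` per bp, 400 kb), from which 50 *consecutive*
common variants (MAF ≥ 0.05) are taken, mimicking a dense genotyping
panel over a contiguous gene with realistic within-gene linkage
disequilibrium and allele-frequency spectrum; genes are mutually
independent (emulating wide between-gene separation). An elementary
matrix of 10,000 individuals is simulated once and 1,000-subject
matrices are drawn from it without replacement.

Why LD matters here and not just cosmetically: with s = 950 ≈ n = 1,000
SNPs, the projected-kernel spectrum of *independent* SNPs is nearly flat
(effective dimension `(Σλ)²/Σλ² ≈ 460`), so the null distribution of `Q`
is extremely concentrated — and the score statistic is normalized by the
*fitted* residual covariance, which absorbs exactly the directions the
flat kernel averages over. The statistic then self-normalizes and the
test becomes severely conservative (empirically 0.5–2% rejections at
α=5%, with matching power collapse), even though with the true Σ it is
exactly calibrated. Haplotype-structured genotypes concentrate the
spectrum (effective dimension ≈ 75–120 here), which restores near-nominal
behaviour (≈ 4.3–5.2% at α=5% in 2,000-replicate runs). The LD-free
Binomial(2, MAF~U(0.05, 0.5)) generator is retained as
`genotype_model="independent"` for unit testing and for isolating this
spectrum effect.

What the generator does *not* emulate: real haplotype-panel resampling
from a finite reference (long-range haplotype sharing), allele-frequency
correlation between causal and tag SNPs of a real gene, and any
population structure. Consequently the *power* levels of the tests under
this generator are much lower at a given per-SNP effect than on
haplotype-resampled human data: a per-SNP effect of β = 0.04 across 9
causal SNPs explains only ~0.1–0.3% of phenotypic variance here, and
even a single-df oracle test that knows the causal set tops out around
40–50% power at n=1,000. Passing null-calibration tests therefore says
the test is valid; the absolute power levels say little about real data,
and power comparisons between configurations are made on paired
(common-random-number) replicates, at effect sizes chosen in the
sensitive power regime of this generator.

## The simulation study engine

`run_study` evaluates a grid of models (kernel × m × effect × β ×
missingness × LMM/ANCOVA). Per genotype matrix it precomputes `GᵀG` and
its eigenbasis, network projections `G·A·L` (19 columns), and the
kernel-PCA columns; per replicate it refits the null model and computes
the p-value through the fastest exact route available: the
diagonal-plus-low-rank CF inversion for linear kernels on complete data,
a gene-dimensional eigenproblem for network kernels, and a
pattern-grouped generic route under missingness. All routes are tested
to agree with the public `test_pathway` / `q_cross_test` API to ≥5
significant digits. Seeds derive deterministically from a master seed
and the replicate coordinates, and exclude the effect size and effect
model, so arms that share a design see identical covariate and noise
draws (paired comparisons). Rejection proportions carry Wald 95%
intervals formatted `[lower; upper]`.

Problem sizes used by the shipped acceptance script: n = 1,000, 19×50
SNPs, 30 genotype subsamples × 100 phenotype replicates = 3,000
replicates per setting (the test suite uses 2,000 replicates per setting
for the calibration checks and 600 paired replicates for the ordering
checks). Power — unlike type I error — varies noticeably
across elementary-matrix draws because the causal-SNP MAF and LD
configuration is drawn once per run.

## Pathway utilities

* Interaction types in edge input (activation/inhibition) are collapsed
  to undirected edges; CHEBI nodes are dropped; duplicate/reversed edges
  merge; self-edges and edges leaving the gene set are dropped with
  warnings.
* Density = |E| / (P(P−1)/2); the adjacency diagonal (self-interaction)
  is excluded from both counts; a single-gene pathway has density 0 by
  convention (warned).
* SNP→gene mapping is positional with a ±window (default 500 kb),
  1-based inclusive ends; BED input (0-based half-open) is converted on
  read. A SNP may map to several genes; unmapped SNPs are logged and
  excluded from kernels.
* `synthesize_topology` rewires a pathway to a target density (within
  one edge) under two constraints: the graph stays connected, and the
  designated causal genes end at or above the median degree ("central
  position"), enforced by a final edge-swap repair phase. The original
  construction algorithm for density variants is not published; this is
  this package's own procedure, deterministic under its seed.
* Effective number of pathways: `W` rows spread each pathway uniformly
  over its genes (`w_rg = 1/P_r`, rows sum to 1), `P_eff` is the
  smallest leading-eigenvalue count of `WWᵀ` reaching a cumulative share
  `c` (default 0.95), and the adjusted level is `0.05/P_eff`. The gene
  universe is the union of the tested pathways only. Fisher combination
  uses `−2Σ ln p ~ χ²(2k)`.

## Numerical choices and degenerate inputs

* Davies accuracy 1e−6; Liu fallback flagged, never silent.
* Eigenvalue truncation at 1e−10·λ_max.
* `V₀` eigenvalues below −1e−6·λ_max raise (null-model misfit); small
  negatives are clipped.
* `Σ̂₀⁻¹` is always applied through per-subject (pattern-grouped) block
  solves; no N_obs×N_obs inverse is ever formed outside the dense test
  oracle.
* KPCA double-centers the kernel before eigendecomposition; component
  signs follow the largest-magnitude-entry-positive convention; if the
  requested component count exceeds the centered rank, the rank
  components are returned with a warning.
* Missing dosages in genotype files are mean-imputed per SNP with a loud
  log line; zero-SNP pathways and rank-deficient designs raise.

## Known limitations

* Gaussian phenotypes only; no binary/count outcomes, no serial (AR1)
  within-subject correlation, no small-sample saddlepoint corrections
  beyond the Liu fallback.
* The network-kernel power advantage reported on haplotype-resampled
  human data does not reproduce under this generator (the gene burden
  captures too little of a 3-of-50-SNP causal signal at realistic
  synthetic LD); the density *ordering* among network kernels is the
  robust, tested property.
* Identifier matching between gene sets, networks and coordinates is
  exact string match.
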