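"""Synthetic genotypes, longitudinal phenotypes, and the power study engine.

Genotypes come in two flavours, organized into equally sized "pseudo-genes"
(default 19 genes x 50 SNPs):

* ``genotype_model="haplotype"`` (default): each pseudo-gene is an
  independent locus simulated with the standard neutral coalescent
  (msprime; Ne = 10,000, mu = 1.25e-8, r = 1e-8 per bp, 100 kb locus), from
  which 50 common variants (MAF >= 0.05) are taken.  This emulates
  haplotype-resampling pipelines: realistic within-gene linkage
  disequilibrium and allele-frequency spectrum, independence between genes.
  The LD structure matters: with s ~ n SNPs the null distribution of the
  score statistic couples to the fitted residual scale, and a spuriously
  flat (LD-free) kernel spectrum makes the test far more conservative than
  haplotype-structured data does.
* ``genotype_model="independent"``: LD-free Binomial(2, MAF) dosages with
  MAF ~ Uniform(maf_range) — useful for unit testing and for isolating
  spectrum effects.

Phenotypes follow the linear mixed model

    y_ij = 0.5 X1_i + 0.25 X2_i + 0.2 t_j + b0_i + b1_i t_j + eps_ij

with ``X1 ~ Bernoulli(0.5)``, ``X2 ~ N(50, 5)``, random intercept/slope
variances 1, their covariance -0.5, and residual variance 1.  Genetic
effects add ``sum_k beta * SNP_ik`` (main), ``sum_k beta * SNP_ik * t_j``
(time interaction), or both (joint) over 3 causal genes x 3 causal SNPs.

Missingness is generated missing-at-random: baseline records are always
kept and later records drop out with a logistic probability in the observed
covariates and time, with the intercept calibrated by bisection to hit the
target overall missing share.

:func:`run_study` estimates type I error and power over many replicates.
Per genotype matrix it precomputes the Gram eigendecomposition once; each
replicate's linear-kernel p-value is then obtained through the
diagonal-plus-low-rank characteristic-function route (see ``_qfmix``), and
network-kernel p-values through the gene-dimensional factor.  Replicates
use common random numbers across effect sizes and effect models (the
underlying null phenotype draw is independent of beta), so power orderings
are compared on shared Monte Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import brentq
from scipy.sparse.linalg import eigsh
from scipy.special import expit

from ._qfmix import davies_pvalue_diag_lowrank, liu_pvalue, mixture_tail
from ._reml import reml_fit
from .data import GenotypeMatrix
from .kernels import network_factor
from .longitudinal import LongitudinalDataset
from .multiplicity import fisher_combine
from .pathway import PathwayNetwork, synthesize_topology

__all__ = [
    "SimulationConfig",
    "StudyModel",
    "simulate_genotypes",
    "draw_subsample",
    "simulate_phenotypes",
    "apply_mar",
    "run_study",
    "gene_level_fisher_comparison",
    "make_simulation_network",
]

ALPHAS = (0.05, 0.01, 0.005, 0.001)


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the phenotype generator."""

    n_subjects: int = 1000
    m: int = 4
    beta_x1: float = 0.5
    beta_x2: float = 0.25
    beta_time: float = 0.2
    var_intercept: float = 1.0
    var_time: float = 1.0
    var_eps: float = 1.0
    cov_intercept_time: float = -0.5
    effect: str = "null"  # null | main | interaction | joint
    beta: float = 0.0
    causal_genes: tuple = (0, 1, 2)
    causal_snps_per_gene: int = 3
    missing_fraction: float = 0.0

    def random_effect_cov(self) -> np.ndarray:
        D = np.array(
            [
                [self.var_intercept, self.cov_intercept_time],
                [self.cov_intercept_time, self.var_time],
            ]
        )
        if np.linalg.eigvalsh(D)[0] < 0:
            raise ValueError("random-effect covariance matrix is not PSD")
        return D

    def causal_columns(self, snps_per_gene: int) -> np.ndarray:
        """Deterministic causal set: first k SNPs of each causal gene."""
        cols = [
            g * snps_per_gene + j
            for g in self.causal_genes
            for j in range(self.causal_snps_per_gene)
        ]
        return np.asarray(cols, dtype=int)


@dataclass(frozen=True)
class StudyModel:
    """One row of the simulation grid (kernel x design x effect)."""

    name: str
    kernel: str = "linear"  # linear | network | size_adjusted_network
    m: int = 4
    analysis: str = "lmm"  # lmm | ancova
    effect_model: str = "null"
    tested_effect: str = "main"  # main | interaction | interaction_adjusted
    beta: float = 0.0
    missing: float = 0.0
    network: PathwayNetwork | None = None


# --------------------------------------------------------------------------
# generators


# Coalescent parameters for the haplotype generator, fixed a priori:
# LD-effective population size of European samples (Tenesa et al. 2007),
# canonical human per-bp mutation and recombination rates, and a locus long
# enough to hold 50+ common variants at this theta.
_COALESCENT_NE = 3_100.0
_MUTATION_RATE = 1.25e-8
_RECOMBINATION_RATE = 1e-8


def _coalescent_gene(n: int, spg: int, min_maf: float, locus_bp: float, rng):
    """Dosages and positions for one coalescent pseudo-gene locus.

    Takes ``spg`` *consecutive* common variants from the middle of the
    locus, mirroring a dense genotyping panel over a contiguous gene region
    (within-gene linkage disequilibrium is therefore realistic; genes are
    simulated independently, i.e. no between-gene LD).
    """
    import msprime

    length = locus_bp
    for _ in range(6):
        ts = msprime.sim_ancestry(
            samples=n,
            ploidy=2,
            population_size=_COALESCENT_NE,
            sequence_length=length,
            recombination_rate=_RECOMBINATION_RATE,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        mts = msprime.sim_mutations(
            ts, rate=_MUTATION_RATE, random_seed=int(rng.integers(1, 2**31 - 1))
        )
        Gh = mts.genotype_matrix()  # sites x 2n haplotypes
        G = (Gh[:, ::2] + Gh[:, 1::2]).astype(np.float32)  # sites x n
        np.clip(G, 0, 2, out=G)  # collapse rare multi-hit sites
        freq = G.mean(axis=1) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        common = np.flatnonzero(maf >= min_maf)
        if common.size >= spg:
            start = (common.size - spg) // 2
            pick = common[start:start + spg]
            pos = mts.sites_position[pick].astype(np.int64)
            return G[pick].T.astype(float), pos
        length *= 2  # unlucky locus: try a longer region
    raise RuntimeError("could not find enough common variants in the locus")


def simulate_genotypes(
    n: int,
    n_genes: int = 19,
    snps_per_gene: int = 50,
    maf_range: tuple = (0.05, 0.5),
    seed=0,
    chromosome: str = "1",
    start_bp: int = 742_000,
    within_gene_spacing: int = 1_000,
    between_gene_spacing: int = 500_000,
    genotype_model: str = "haplotype",
    locus_bp: float = 4e5,
) -> GenotypeMatrix:
    """Pseudo-gene genotypes: coalescent haplotype loci or LD-free binomial."""
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
    rng = np.random.default_rng(seed)
    s = n_genes * snps_per_gene
    gene_index = np.repeat(np.arange(n_genes), snps_per_gene)
    if genotype_model == "haplotype":
        blocks, positions = [], []
        offset = start_bp
        for _ in range(n_genes):
            block, pos = _coalescent_gene(n, snps_per_gene, lo, locus_bp, rng)
            blocks.append(block)
            positions.append(offset + pos)
            offset += int(locus_bp) + between_gene_spacing
        values = np.concatenate(blocks, axis=1)
        positions = np.concatenate(positions)
    elif genotype_model == "independent":
        maf = rng.uniform(lo, hi, size=s)
        values = rng.binomial(2, maf, size=(n, s)).astype(float)
        within = np.tile(np.arange(snps_per_gene), n_genes)
        positions = (
            start_bp
            + gene_index * (between_gene_spacing + snps_per_gene * within_gene_spacing)
            + within * within_gene_spacing
        )
    else:
        raise ValueError(f"unknown genotype_model {genotype_model!r}")
    snp_ids = [f"snp{i + 1}" for i in range(s)]
    return GenotypeMatrix(
        values=values,
        snp_ids=snp_ids,
        positions=positions,
        chromosome=np.full(s, chromosome, dtype=object),
        gene_index=gene_index,
    )


def draw_subsample(elementary: GenotypeMatrix, n_sub: int, seed=0) -> GenotypeMatrix:
    """Rows sampled without replacement from the elementary matrix."""
    if n_sub > elementary.n_subjects:
        raise ValueError("subsample larger than the elementary matrix")
    rng = np.random.default_rng(seed)
    rows = rng.choice(elementary.n_subjects, size=n_sub, replace=False)
    return GenotypeMatrix(
        values=elementary.values[rows],
        snp_ids=list(elementary.snp_ids),
        positions=elementary.positions,
        chromosome=elementary.chromosome,
        gene_index=elementary.gene_index,
        subject_ids=np.arange(n_sub),
    )


def _draw_arrays(G: np.ndarray, snps_per_gene: int, config: SimulationConfig, rng):
    """(X1, X2, Y) with Y an n x m phenotype matrix (complete)."""
    n, m = config.n_subjects, config.m
    if m < 2:
        raise ValueError("longitudinal generator needs m >= 2")
    if G.shape[0] != n:
        raise ValueError("genotype rows do not match n_subjects")
    t = np.arange(m, dtype=float)
    X1 = rng.binomial(1, 0.5, size=n).astype(float)
    X2 = rng.normal(50.0, 5.0, size=n)
    D = config.random_effect_cov()
    b = rng.multivariate_normal(np.zeros(2), D, size=n)
    eps = rng.normal(0.0, np.sqrt(config.var_eps), size=(n, m))
    Y = (
        config.beta_x1 * X1[:, None]
        + config.beta_x2 * X2[:, None]
        + config.beta_time * t[None, :]
        + b[:, [0]]
        + b[:, [1]] * t[None, :]
        + eps
    )
    if config.effect != "null" and config.beta != 0.0:
        dosage_sum = G[:, config.causal_columns(snps_per_gene)].sum(axis=1)
        if config.effect in ("main", "joint"):
            Y += config.beta * dosage_sum[:, None]
        if config.effect in ("interaction", "joint"):
            Y += config.beta * dosage_sum[:, None] * t[None, :]
    elif config.effect not in ("null", "main", "interaction", "joint"):
        raise ValueError(f"unknown effect model {config.effect!r}")
    return X1, X2, Y


def _mar_mask(X1, X2, m: int, fraction: float, rng) -> np.ndarray:
    """n x m boolean "observed" mask; baseline always observed, MAR beyond."""
    n = X1.size
    mask = np.ones((n, m), dtype=bool)
    if fraction == 0.0:
        return mask
    if not 0.0 <= fraction <= 0.9:
        raise ValueError("missing fraction must lie in [0, 0.9]")
    t = np.arange(1, m, dtype=float)
    z = (
        0.5 * X1[:, None]
        + 0.3 * ((X2[:, None] - 50.0) / 5.0)
        + 0.3 * (t[None, :] - 1.0)
    )

    def mean_miss(a):
        return float(expit(a + z).mean()) - fraction

    a = brentq(mean_miss, -30.0, 30.0, xtol=1e-10)
    miss = rng.random((n, m - 1)) < expit(a + z)
    mask[:, 1:] = ~miss
    return mask


def _to_dataset(X1, X2, Y, mask) -> LongitudinalDataset:
    n, m = Y.shape
    t = np.tile(np.arange(m), n)
    table = pd.DataFrame(
        {
            "subject_id": np.repeat(np.arange(n), m),
            "time": t,
            "y": np.where(mask.ravel(), Y.ravel(), np.nan),
            "x1": np.repeat(X1, m),
            "x2": np.repeat(X2, m),
        }
    )
    return LongitudinalDataset(table, covariates=["x1", "x2"])


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimulationConfig, seed=0
) -> LongitudinalDataset:
    """Longitudinal phenotypes under the configured effect model (complete)."""
    rng = np.random.default_rng(seed)
    spg = _snps_per_gene(genotypes)
    X1, X2, Y = _draw_arrays(genotypes.values, spg, config, rng)
    mask = np.ones(Y.shape, dtype=bool)
    return _to_dataset(X1, X2, Y, mask)


def apply_mar(
    dataset: LongitudinalDataset, missing_fraction: float, seed=0
) -> LongitudinalDataset:
    """Missing-at-random dropout of non-baseline records.

    The dropout probability is logistic in X1, X2 and time (never in the
    removed y itself), with the intercept calibrated so the expected missing
    share of non-baseline records equals ``missing_fraction``.
    """
    if missing_fraction == 0.0:
        return dataset
    rng = np.random.default_rng(seed)
    table = dataset.table.sort_values(["subject_id", "time"]).reset_index(drop=True)
    n = table["subject_id"].nunique()
    m = int(table["time"].max()) + 1
    if len(table) != n * m:
        raise ValueError("apply_mar expects a complete rectangular dataset")
    X1 = table.loc[table["time"] == 0, "x1"].to_numpy(float)
    X2 = table.loc[table["time"] == 0, "x2"].to_numpy(float)
    mask = _mar_mask(X1, X2, m, missing_fraction, rng)
    out = table.copy()
    out.loc[~mask.ravel(), "y"] = np.nan
    return LongitudinalDataset(out, covariates=list(dataset.covariates))


def _snps_per_gene(gm: GenotypeMatrix) -> int:
    if gm.gene_index is None:
        return gm.n_snps
    counts = np.bincount(gm.gene_index)
    if not (counts == counts[0]).all():
        raise ValueError("pseudo-genes must be equally sized")
    return int(counts[0])


def make_simulation_network(
    n_genes: int = 19,
    density: float = 0.46,
    causal_genes: tuple = (0, 1, 2),
    seed: int = 2023,
) -> PathwayNetwork:
    """Synthetic connected pathway topology with central causal genes.

    A stand-in for a real curated pathway: a ring backbone (connectivity)
    rewired to the target density under the constraint that the causal
    genes stay at or above the median degree.
    """
    genes = [f"g{i + 1}" for i in range(n_genes)]
    ring = PathwayNetwork(
        genes,
        {frozenset((genes[i], genes[(i + 1) % n_genes])) for i in range(n_genes)},
        name="ring",
    )
    causal = [genes[i] for i in causal_genes]
    net = synthesize_topology(ring, density, causal, seed=seed)
    return replace_name(net, f"synthetic_d{density:g}")


def replace_name(net: PathwayNetwork, name: str) -> PathwayNetwork:
    return PathwayNetwork(net.gene_ids, set(net.edges), name=name)


# --------------------------------------------------------------------------
# fast per-replicate testing machinery


@dataclass
class _MatrixContext:
    """Per-genotype-matrix precomputation shared across phenotype replicates."""

    G: np.ndarray
    snps_per_gene: int
    gram_eig: tuple | None = None  # (d, V) of G^T G
    kpca2: np.ndarray | None = None
    net_proj: dict = field(default_factory=dict)  # network name -> G @ A L

    def gram(self):
        if self.gram_eig is None:
            d, V = np.linalg.eigh(self.G.T @ self.G)
            self.gram_eig = (np.clip(d, 0.0, None), V)
        return self.gram_eig

    def kpca(self):
        if self.kpca2 is None:
            K = self.G @ self.G.T
            Kc = K - K.mean(0) - K.mean(1)[:, None] + K.mean()
            w, V = eigsh(Kc, k=2, which="LA")
            order = np.argsort(w)[::-1]
            w, V = w[order], V[:, order]
            comps = V * np.sqrt(np.clip(w, 0.0, None))
            flip = np.sign(comps[np.abs(comps).argmax(axis=0), np.arange(2)])
            self.kpca2 = comps * flip
        return self.kpca2

    def projected(self, annotation, network, size_adjust: bool) -> np.ndarray:
        key = (network.name, size_adjust)
        if key not in self.net_proj:
            F, _ = network_factor(annotation, network, size_adjust)
            self.net_proj[key] = self.G @ F
        return self.net_proj[key]


def _complete_design(X1, X2, m: int, extra=None):
    """Stacked (n, m, p) fixed-effect design: 1, x1, x2, [extras], t."""
    n = X1.size
    t = np.arange(m, dtype=float)
    cols = [np.ones((n, m)), np.broadcast_to(X1[:, None], (n, m)),
            np.broadcast_to(X2[:, None], (n, m))]
    if extra is not None:
        for j in range(extra.shape[1]):
            cols.append(np.broadcast_to(extra[:, [j]], (n, m)))
    cols.append(np.broadcast_to(t[None, :], (n, m)))
    return np.stack(cols, axis=2)


def _fit_complete(Xnmp, Y):
    """REML fit on complete data via the generic engine."""
    n, m, p = Xnmp.shape
    subj = np.repeat(np.arange(n), m)
    time = np.tile(np.arange(m, dtype=float), n)
    return reml_fit(subj, time, Y.ravel(), Xnmp.reshape(n * m, p))


def _lmm_pvalue_complete_linear(fit, ctx: _MatrixContext, Xnmp, Y, interaction):
    """Linear-kernel score test on complete data, no eigendecomposition.

    Uses B^T Sigma^-1 B = w * G^T G with w = v' Sigma_m^-1 v (v = 1 or t),
    and the rank-p fixed-effect downdate in the precomputed Gram eigenbasis.
    """
    n, m, p = Xnmp.shape
    t = np.arange(m, dtype=float)
    Z = np.column_stack([np.ones(m), t])
    Sm = Z @ fit.D @ Z.T + fit.sigma_eps2 * np.eye(m)
    Smi = np.linalg.inv(Sm)
    v = t if interaction else np.ones(m)
    Smiv = Smi @ v
    w = float(v @ Smiv)
    R = (Y - np.einsum("nmp,p->nm", Xnmp, fit.beta))
    u = R @ Smiv  # (n,)
    Btr = ctx.G.T @ u
    Q = 0.5 * float(Btr @ Btr)

    Xtv = np.einsum("nmp,m->np", Xnmp, Smiv)  # per-subject X_i' Sm^-1 v
    C = Xtv.T @ ctx.G  # (p, s)
    M = np.einsum("nmp,mk,nkq->pq", Xnmp, Smi, Xnmp, optimize=True)
    L = np.linalg.cholesky(M)
    W = solve_triangular(L, C, lower=True)  # (p, s); C' M^-1 C = W' W
    d, V = ctx.gram()
    U = V.T @ W.T / np.sqrt(2.0)
    a = 0.5 * w * d
    pval, ok = davies_pvalue_diag_lowrank(Q, a, U)
    if not ok:
        lam = np.linalg.eigvalsh(np.diag(a) - U @ U.T)
        pval = liu_pvalue(Q, np.clip(lam, 0.0, None))
    return float(min(max(pval, 1e-15), 1.0))


def _lmm_pvalue_factor(fit, B, Xobs, resid):
    """Score test for an explicit observation-level factor B (few columns)."""
    SiB = fit.apply_sigma_inv(B)
    SiX = fit.apply_sigma_inv(Xobs)
    M = Xobs.T @ SiX
    C = Xobs.T @ SiB
    A = 0.5 * (B.T @ SiB - C.T @ cho_solve(cho_factor(M), C))
    lam = np.clip(np.linalg.eigvalsh(A), 0.0, None)
    Sir = fit.apply_sigma_inv(resid)
    Q = 0.5 * float((B.T @ Sir) @ (B.T @ Sir))
    p, _ = mixture_tail(Q, lam)
    return p


def _ancova_pvalue(ctx: _MatrixContext, X1, X2, Y, Gproj=None):
    """ANCOVA kernel score test: OLS of y(t1) on covariates + y(t0).

    ``Gproj`` switches to a network-projected factor; otherwise the linear
    kernel runs through the Gram eigenbasis route.
    """
    y0, y1 = Y[:, 0], Y[:, 1]
    n = y0.size
    X = np.column_stack([np.ones(n), X1, X2, y0])
    beta, _, _, _ = np.linalg.lstsq(X, y1, rcond=None)
    r = y1 - X @ beta
    s2 = float(r @ r) / (n - X.shape[1])
    if Gproj is not None:
        B = Gproj
        H = X @ np.linalg.solve(X.T @ X, X.T @ B)
        A = (B.T @ B - B.T @ H) / (2.0 * s2)
        lam = np.clip(np.linalg.eigvalsh(A), 0.0, None)
        Q = float((B.T @ r) @ (B.T @ r)) / (2.0 * s2 * s2)
        p, _ = mixture_tail(Q, lam)
        return p
    Btr = ctx.G.T @ r
    Q = float(Btr @ Btr) / (2.0 * s2 * s2)
    d, V = ctx.gram()
    XtG = X.T @ ctx.G
    L = np.linalg.cholesky(X.T @ X)
    W = solve_triangular(L, XtG, lower=True)
    U = V.T @ W.T / np.sqrt(2.0 * s2)
    a = d / (2.0 * s2)
    pval, ok = davies_pvalue_diag_lowrank(Q, a, U)
    if not ok:
        lam = np.linalg.eigvalsh(np.diag(a) - U @ U.T)
        pval = liu_pvalue(Q, np.clip(lam, 0.0, None))
    return float(min(max(pval, 1e-15), 1.0))


def _replicate_pvalue(model: StudyModel, ctx, annotation, X1, X2, Y, mask):
    """p-value of one simulated replicate under one study model."""
    if model.analysis == "ancova":
        return _ancova_pvalue(
            ctx,
            X1,
            X2,
            Y,
            Gproj=None
            if model.kernel == "linear"
            else ctx.projected(annotation, model.network, model.kernel.startswith("size")),
        )
    complete = bool(mask.all())
    extra = ctx.kpca() if model.tested_effect == "interaction_adjusted" else None
    Xnmp = _complete_design(X1, X2, model.m, extra)
    n, m, p = Xnmp.shape
    interaction = model.tested_effect != "main"
    if complete:
        fit = _fit_complete(Xnmp, Y)
        if model.kernel == "linear":
            return _lmm_pvalue_complete_linear(fit, ctx, Xnmp, Y, interaction)
        Gp = ctx.projected(annotation, model.network, model.kernel.startswith("size"))
        t = np.arange(m, dtype=float)
        v = t if interaction else np.ones(m)
        B = np.repeat(Gp, m, axis=0) * np.tile(v, n)[:, None]
        Xobs = Xnmp.reshape(n * m, p)
        resid = (Y - np.einsum("nmp,p->nm", Xnmp, fit.beta)).ravel()
        return _lmm_pvalue_factor(fit, B, Xobs, resid)
    # incomplete data: subset observed rows, generic factor route
    rows = mask.ravel()
    subj = np.repeat(np.arange(n), m)[rows]
    time = np.tile(np.arange(m, dtype=float), n)[rows]
    Xobs = Xnmp.reshape(n * m, p)[rows]
    y = Y.ravel()[rows]
    fit = reml_fit(subj, time, y, Xobs)
    if model.kernel == "linear":
        Gobs = ctx.G[subj]
    else:
        Gobs = ctx.projected(
            annotation, model.network, model.kernel.startswith("size")
        )[subj]
    B = Gobs * time[:, None] if interaction else Gobs
    resid = y - Xobs @ fit.beta
    return _lmm_pvalue_factor(fit, B, Xobs, resid)


# --------------------------------------------------------------------------
# study driver


def _wald_ci(k: int, nrep: int):
    phat = k / nrep
    half = 1.96 * np.sqrt(phat * (1 - phat) / nrep)
    return max(phat - half, 0.0), min(phat + half, 1.0)


def run_study(
    models: list[StudyModel],
    n_subjects: int = 1000,
    n_matrices: int = 10,
    reps_per_matrix: int = 100,
    n_genes: int = 19,
    snps_per_gene: int = 50,
    elementary_size: int = 10_000,
    seed: int = 1,
    alphas=ALPHAS,
    config: SimulationConfig | None = None,
    collect_pvalues: bool = False,
    genotype_model: str = "haplotype",
):
    """Estimate rejection proportions (type I error / power) per model row.

    Each model row is evaluated on ``n_matrices`` genotype subsamples drawn
    from one elementary matrix, with ``reps_per_matrix`` phenotype
    replicates per subsample.  Seeds derive deterministically from ``seed``
    and the replicate coordinates; models sharing a data configuration see
    identical phenotype draws (common random numbers).

    Returns a DataFrame with one row per model: rejection proportion and a
    Wald 95% CI (formatted "[lower; upper]") at each alpha; optionally the
    raw p-values.
    """
    base_cfg = config or SimulationConfig(n_subjects=n_subjects)
    elementary = simulate_genotypes(
        elementary_size,
        n_genes,
        snps_per_gene,
        seed=[seed, 7],
        genotype_model=genotype_model,
    )
    from .pathway import AnnotationMap

    annotations = {}
    contexts = []
    for j in range(n_matrices):
        gm = draw_subsample(elementary, n_subjects, seed=[seed, 11, j])
        contexts.append(_MatrixContext(gm.values, snps_per_gene))

    def annotation_for(network):
        if network.name not in annotations:
            gene_ids = network.gene_ids
            inc = np.zeros((n_genes * snps_per_gene, len(gene_ids)))
            gi = np.repeat(np.arange(n_genes), snps_per_gene)
            inc[np.arange(inc.shape[0]), gi] = 1.0
            annotations[network.name] = AnnotationMap(
                [f"snp{i + 1}" for i in range(inc.shape[0])], list(gene_ids), inc
            )
        return annotations[network.name]

    records = []
    pvalue_store = {}
    for model in models:
        if model.network is not None and len(model.network.gene_ids) != n_genes:
            raise ValueError(f"model {model.name}: network size mismatch")
        cfg = replace(
            base_cfg,
            n_subjects=n_subjects,
            m=model.m,
            effect=model.effect_model,
            beta=model.beta,
            missing_fraction=model.missing,
        )
        ann = annotation_for(model.network) if model.network is not None else None
        pvals = np.empty(n_matrices * reps_per_matrix)
        k = 0
        for j, ctx in enumerate(contexts):
            for r in range(reps_per_matrix):
                rng = np.random.default_rng([seed, 101, cfg.m, j, r])
                X1, X2, Y = _draw_arrays(ctx.G, snps_per_gene, cfg, rng)
                if cfg.missing_fraction > 0:
                    mrng = np.random.default_rng(
                        [seed, 202, int(round(cfg.missing_fraction * 100)), cfg.m, j, r]
                    )
                    mask = _mar_mask(X1, X2, cfg.m, cfg.missing_fraction, mrng)
                else:
                    mask = np.ones(Y.shape, dtype=bool)
                try:
                    pvals[k] = _replicate_pvalue(model, ctx, ann, X1, X2, Y, mask)
                except Exception:  # failed replicate: excluded, counted
                    pvals[k] = np.nan
                k += 1
        ok = pvals[~np.isnan(pvals)]
        row = {"model": model.name, "effect_model": model.effect_model,
               "tested_effect": model.tested_effect, "kernel": model.kernel,
               "m": model.m, "beta": model.beta, "missing": model.missing,
               "n_replicates": ok.size, "n_failed": int(np.isnan(pvals).sum())}
        for a in alphas:
            kk = int((ok < a).sum())
            lo, hi = _wald_ci(kk, ok.size)
            row[f"reject@{a:g}"] = kk / ok.size
            row[f"ci@{a:g}"] = f"[{100 * lo:.2f}; {100 * hi:.2f}]"
        records.append(row)
        if collect_pvalues:
            pvalue_store[model.name] = ok.copy()
    out = pd.DataFrame.from_records(records)
    if collect_pvalues:
        return out, pvalue_store
    return out


def gene_level_fisher_comparison(
    dataset: LongitudinalDataset, genotypes: GenotypeMatrix, gene_partition=None
) -> float:
    """Gene-by-gene main-effect tests combined to a pathway p-value.

    Mirrors comparing against a single-gene longitudinal kernel method:
    each gene is tested with the linear kernel and the per-gene p-values
    are combined with Fisher's method.
    """
    from .score_test import test_pathway

    if gene_partition is None:
        if genotypes.gene_index is None:
            raise ValueError("no gene partition available")
        gene_partition = [
            np.flatnonzero(genotypes.gene_index == g)
            for g in np.unique(genotypes.gene_index)
        ]
    pvals = []
    for cols in gene_partition:
        sub = GenotypeMatrix(
            genotypes.values[:, cols],
            [genotypes.snp_ids[c] for c in cols],
            subject_ids=genotypes.subject_ids,
        )
        res = test_pathway(dataset, sub, kernel="linear", effect="main")
        pvals.append(res.p_value)
    return fisher_combine(np.asarray(pvals))
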