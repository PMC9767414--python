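"""Variance-component score tests for pathway association.

Cross-sectional statistic (one record per subject):

    Q_cross = 1/(2 sigma_eps^2) * (y - X beta0)^T K (y - X beta0)

Longitudinal statistic (observation level, ``Sigma0`` from the null LMM):

    Q_long = 1/2 * (y - X beta0)^T Sigma0^{-1} K Sigma0^{-1} (y - X beta0)

Under H0: tau = 0 the statistic follows a mixture ``sum_l lambda_l chi2_1``
where ``lambda_l`` are the eigenvalues of

    1/2 * V0^{1/2} Sigma0^{-1} K Sigma0^{-1} V0^{1/2},
    V0 = Sigma0 - X (X^T Sigma0^{-1} X)^{-1} X^T.

Note the algebraic identity ``Sigma0^{-1} V0 Sigma0^{-1} = P0`` with
``P0 = Sigma0^{-1} - Sigma0^{-1} X (X^T Sigma0^{-1} X)^{-1} X^T Sigma0^{-1}``
and ``P0 Sigma0 P0 = P0``: the eigenvalue matrix above therefore has the
same spectrum as the conventional projected kernel ``(1/2) K^{1/2} P0
K^{1/2}``, and with a kernel factorization ``K = B B^T`` the nonzero
eigenvalues are those of the small symmetric matrix ``(1/2) B^T P0 B``.
That s x s reduction is the default computational path; the dense formula
is retained for verification.  P-values come from Davies-type
characteristic-function inversion with a Liu moment-matching fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._qfmix import mixture_tail
from .data import GenotypeMatrix
from .kernels import kpca_components, network_factor, quadratic_kernel
from .longitudinal import (
    LongitudinalDataset,
    NullModelFit,
    fit_ancova_null,
    fit_null_lmm,
)
from .pathway import AnnotationMap, PathwayNetwork

__all__ = [
    "ScoreTestResult",
    "q_long",
    "q_cross",
    "null_eigenvalues",
    "mixture_pvalue",
    "test_pathway",
    "q_cross_test",
]

EFFECTS = ("main", "interaction", "interaction_adjusted")
_EIG_DROP = 1e-10
_V0_TOL = 1e-6


@dataclass
class ScoreTestResult:
    Q: float
    eigenvalues: np.ndarray
    p_value: float
    effect: str
    kernel: str
    pvalue_method: str
    n_subjects: int
    n_observations: int
    n_snps: int
    repaired_network: bool = False
    n_genes: int | None = None

    def __post_init__(self):
        if self.Q < 0:
            raise ValueError("score statistic must be nonnegative")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p-value outside (0, 1]")


def q_long(y, X, beta0, sigma0_inverse, K) -> float:
    """``Q_long = 1/2 r^T Sigma0^{-1} K Sigma0^{-1} r`` with ``r = y - X beta0``."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    K = np.asarray(K, float)
    Si = np.asarray(sigma0_inverse, float)
    if X.shape[0] != y.size or K.shape != (y.size, y.size) or Si.shape != K.shape:
        raise ValueError("non-conformable dimensions")
    r = y - X @ np.asarray(beta0, float)
    sr = Si @ r
    return float(0.5 * sr @ K @ sr)


def q_cross(y, X, beta0, sigma_eps2, K) -> float:
    """``Q_cross = 1/(2 sigma_eps^2) r^T K r``."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    r = y - X @ np.asarray(beta0, float)
    K = np.asarray(K, float)
    if K.shape != (y.size, y.size):
        raise ValueError("non-conformable dimensions")
    return float(r @ K @ r / (2.0 * sigma_eps2))


def null_eigenvalues(Sigma0, X, K) -> np.ndarray:
    """Eigenvalues of ``1/2 V0^{1/2} Sigma0^{-1} K Sigma0^{-1} V0^{1/2}``.

    Dense reference implementation, evaluated exactly as printed.  Raises if
    ``V0`` has an eigenvalue below ``-1e-6 * max`` (model misfit); small
    negatives are clipped.  Eigenvalues below ``1e-10 * max`` are dropped.
    """
    Sigma0 = np.asarray(Sigma0, float)
    X = np.asarray(X, float)
    K = np.asarray(K, float)
    Si = np.linalg.inv(Sigma0)
    XtSiX = X.T @ Si @ X
    V0 = Sigma0 - X @ np.linalg.solve(XtSiX, X.T)
    w, V = np.linalg.eigh((V0 + V0.T) / 2)
    if w[0] < -_V0_TOL * max(w[-1], 1.0):
        raise ValueError(
            f"V0 is not PSD (min eigenvalue {w[0]:.3g}); null model misfit"
        )
    V0h = (V * np.sqrt(np.clip(w, 0.0, None))) @ V.T
    M = 0.5 * V0h @ Si @ K @ Si @ V0h
    lam = np.linalg.eigvalsh((M + M.T) / 2)[::-1]
    return _clean_eigenvalues(lam)


def _clean_eigenvalues(lam: np.ndarray) -> np.ndarray:
    lam = np.asarray(lam, float)
    if lam.size == 0:
        return lam
    top = lam.max()
    if top <= 0:
        return np.array([])
    lam = np.clip(lam, 0.0, None)
    lam = lam[lam > _EIG_DROP * top]
    return np.sort(lam)[::-1]


def _eigenvalues_factored(fit: NullModelFit, B: np.ndarray) -> np.ndarray:
    """Nonzero mixture weights via the s x s problem ``1/2 B^T P0 B``."""
    SiB = fit.apply_sigma_inv(B)
    SiX = fit.apply_sigma_inv(fit.X)
    M = fit.X.T @ SiX
    C = fit.X.T @ SiB
    A = 0.5 * (B.T @ SiB - C.T @ np.linalg.solve(M, C))
    lam = np.linalg.eigvalsh((A + A.T) / 2)[::-1]
    return _clean_eigenvalues(lam)


def mixture_pvalue(Q: float, eigenvalues) -> tuple[float, str]:
    """Tail probability ``P(sum lambda_l chi2_1 > Q)`` (Davies, Liu fallback)."""
    lam = np.asarray(eigenvalues, float)
    if lam.size == 0 or lam.max() <= 0:
        raise ValueError("all eigenvalues are zero; test is degenerate")
    return mixture_tail(Q, lam)


def _observation_factor(
    G: np.ndarray,
    subject: np.ndarray,
    time: np.ndarray,
    effect: str,
    kernel: str,
    annotation: AnnotationMap | None,
    network: PathwayNetwork | None,
):
    """Observation-level factor B with K = B B^T (None for quadratic)."""
    rows = G[subject]
    if effect in ("interaction", "interaction_adjusted"):
        rows = rows * time[:, None]
    repaired = False
    if kernel == "linear":
        B = rows
    elif kernel in ("network", "size_adjusted_network"):
        if annotation is None or network is None:
            raise ValueError("network kernel needs an annotation and a network")
        F, repaired = network_factor(
            annotation, network, size_adjust=(kernel == "size_adjusted_network")
        )
        B = rows @ F
    elif kernel == "quadratic":
        return None, rows, False
    else:
        raise ValueError(f"unknown kernel kind {kernel!r}")
    return B, rows, repaired


def _align_genotypes(genotypes, dataset: LongitudinalDataset) -> np.ndarray:
    """Genotype rows in the order subjects are factorized in the dataset."""
    obs = dataset.observed()
    subject_order = obs["subject_id"].unique()
    if isinstance(genotypes, GenotypeMatrix):
        return genotypes.rows_for(subject_order)
    G = np.asarray(genotypes, float)
    if G.shape[0] != len(subject_order):
        raise ValueError(
            "genotype matrix rows do not match the dataset's subjects; "
            "pass a GenotypeMatrix with subject ids for explicit alignment"
        )
    return G


def test_pathway(
    dataset: LongitudinalDataset,
    genotypes,
    kernel: str = "linear",
    effect: str = "main",
    annotation: AnnotationMap | None = None,
    network: PathwayNetwork | None = None,
    n_pcs: int = 2,
) -> ScoreTestResult:
    """Longitudinal pathway score test.

    effect="main"                  tests the genetic main-effect kernel;
    effect="interaction"           tests the time-by-genotype kernel without
                                   main-effect adjustment;
    effect="interaction_adjusted"  first adds the top ``n_pcs`` kernel-PCA
                                   components of the main-effect kernel as
                                   fixed effects, then tests the interaction
                                   kernel.

    The null model never involves the pathway, so the LMM is refit only when
    the fixed-effect design changes (the adjusted variant).
    """
    if effect not in EFFECTS:
        raise ValueError(f"effect must be one of {EFFECTS}")
    G = _align_genotypes(genotypes, dataset)
    if annotation is not None:
        keep = annotation.mapped_snps
        if not keep.any():
            raise ValueError("pathway has zero mapped SNPs")
    if G.shape[1] == 0:
        raise ValueError("pathway has zero mapped SNPs")

    subj, t, y, X = dataset.design()
    if effect != "main" and np.unique(t).size < 2:
        raise ValueError("interaction test needs non-constant time")

    extra_fixed = None
    if effect == "interaction_adjusted":
        B1, _, _ = _observation_factor(G, subj, t, "main", kernel, annotation, network)
        if B1 is None:  # quadratic: dense kernel
            K1 = quadratic_kernel(G[subj], level="observation").values
        else:
            K1 = B1 @ B1.T
        extra_fixed = kpca_components(K1, n_pcs)

    fit = _fit_with_extra(dataset, extra_fixed)
    B, rows, repaired = _observation_factor(
        G, subj, t, effect, kernel, annotation, network
    )
    r = fit.residuals
    Sir = fit.apply_sigma_inv(r)
    if B is not None:
        Q = float(0.5 * np.sum((B.T @ Sir) ** 2))
        lam = _eigenvalues_factored(fit, B)
    else:
        K = quadratic_kernel(rows, level="observation").values
        Q = float(0.5 * Sir @ K @ Sir)
        lam = null_eigenvalues(fit.sigma0_dense(), fit.X, K)
    p, method = mixture_pvalue(Q, lam)
    return ScoreTestResult(
        Q=Q,
        eigenvalues=lam,
        p_value=p,
        effect=effect,
        kernel=kernel,
        pvalue_method=method,
        n_subjects=fit.n_subjects,
        n_observations=fit.n_obs,
        n_snps=G.shape[1],
        repaired_network=repaired,
        n_genes=len(network.gene_ids) if network is not None else None,
    )


def _fit_with_extra(dataset: LongitudinalDataset, extra_fixed) -> NullModelFit:
    if extra_fixed is None:
        return fit_null_lmm(dataset)
    from ._reml import reml_fit

    subj, t, y, X = dataset.design()
    X = np.column_stack([X, extra_fixed])
    res = reml_fit(subj, t, y, X)
    return NullModelFit(
        kind="lmm",
        beta0=res.beta,
        D0=res.D,
        sigma_eps2=res.sigma_eps2,
        X=X,
        residuals=y - X @ res.beta,
        loglik=res.loglik,
        converged=res.converged,
        boundary=res.boundary,
        n_subjects=res.n_subjects,
        n_obs=res.n_obs,
        subject=subj,
        time=t,
        _reml=res,
    )


def q_cross_test(
    dataset: LongitudinalDataset,
    genotypes,
    kernel: str = "linear",
    effect: str = "main",
    annotation: AnnotationMap | None = None,
    network: PathwayNetwork | None = None,
) -> ScoreTestResult:
    """Cross-sectional (ANCOVA) kernel score test for a pre/post design.

    The null is OLS of the follow-up measurement on covariates plus the
    baseline measurement.  For effect="interaction" the genotype rows are
    scaled by the follow-up time value; since that is a common positive
    constant across subjects, the p-value coincides with the main-effect
    test on the same data (scale invariance of the score test) — the two
    effect labels differ only in how the simulated data were generated.
    """
    fit = fit_ancova_null(dataset)
    obs = dataset.observed()
    t1 = sorted(obs["time"].unique())[1]
    wide = obs.pivot(index="subject_id", columns="time", values="y").dropna()
    subject_order = wide.index.to_numpy()
    if isinstance(genotypes, GenotypeMatrix):
        G = genotypes.rows_for(subject_order)
    else:
        G = np.asarray(genotypes, float)
        full_order = obs["subject_id"].unique()
        pos = {s: i for i, s in enumerate(full_order)}
        G = G[[pos[s] for s in subject_order]]
    if G.shape[0] != fit.n_subjects:
        raise ValueError("genotypes do not align with complete-pair subjects")

    rows = G * float(t1) if effect.startswith("interaction") else G
    if kernel == "linear":
        B = rows
        repaired = False
    elif kernel in ("network", "size_adjusted_network"):
        F, repaired = network_factor(
            annotation, network, size_adjust=(kernel == "size_adjusted_network")
        )
        B = rows @ F
    elif kernel == "quadratic":
        B, repaired = None, False
    else:
        raise ValueError(f"unknown kernel kind {kernel!r}")

    # The reported statistic is Q_cross = r^T K r / (2 sigma^2); its null
    # mixture weights are sigma^2 times the Sigma0 = sigma^2 I eigenvalue
    # formula (equivalently: p is computed from the Q_long form of the same
    # quadratic form, which is identical for every consistent pairing).
    r = fit.residuals
    if B is not None:
        Q = float((B.T @ r) @ (B.T @ r) / (2.0 * fit.sigma_eps2))
        lam = fit.sigma_eps2 * _eigenvalues_factored(fit, B)
    else:
        K = quadratic_kernel(rows).values
        Q = q_cross(wide[t1].to_numpy(float), fit.X, fit.beta0, fit.sigma_eps2, K)
        lam = fit.sigma_eps2 * null_eigenvalues(fit.sigma0_dense(), fit.X, K)
    p, method = mixture_pvalue(Q, lam)
    return ScoreTestResult(
        Q=Q,
        eigenvalues=lam,
        p_value=p,
        effect=effect,
        kernel=kernel,
        pvalue_method=method,
        n_subjects=fit.n_subjects,
        n_observations=fit.n_obs,
        n_snps=G.shape[1],
        repaired_network=repaired,
        n_genes=len(network.gene_ids) if network is not None else None,
    )
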