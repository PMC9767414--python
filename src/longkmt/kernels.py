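"""Genetic similarity kernels for pathway score tests.

The kernel matrix ``K`` holds, for each pair of individuals (or of
observations, in the longitudinal expansion), a similarity score computed
from their genotype vectors.  Available kernels:

* linear:       ``K = G G^T``
* quadratic:    ``K_ij = (c + g_i^T g_j)^d`` with default ``c = 1, d = 2``
* network:      ``K = G A N A^T G^T`` (adjacency ``N``, annotation ``A``)
* size-adjusted network: as above with ``A`` columns scaled by ``1/sqrt(c_g)``

The network adjacency is repaired to positive semidefiniteness by a minimal
diagonal shift before use, so every kernel constructed here is PSD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .pathway import AnnotationMap, PathwayNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "KernelMatrix",
    "RepairedAdjacency",
    "linear_kernel",
    "quadratic_kernel",
    "network_kernel",
    "network_factor",
    "ensure_psd",
    "expand_to_observations",
    "kpca_components",
]

KERNEL_KINDS = ("linear", "quadratic", "network", "size_adjusted_network")


@dataclass
class KernelMatrix:
    values: np.ndarray
    kind: str
    level: str = "subject"  # or "observation"
    repaired_network: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kernel matrix must be square")
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def validate(self, sym_tol: float = 1e-10, psd_tol: float = 1e-8) -> None:
        """Raise if the symmetry / PSD invariants are violated."""
        scale = max(np.abs(self.values).max(), 1.0)
        if np.abs(self.values - self.values.T).max() > sym_tol * scale:
            raise ValueError("kernel matrix is not symmetric")
        w = np.linalg.eigvalsh(self.values)
        if w[0] < -psd_tol * max(w[-1], 1.0):
            raise ValueError(f"kernel matrix is not PSD (min eig {w[0]:.3g})")

    def normalized(self) -> "KernelMatrix":
        """Trace-normalized copy (trace(K) = n).

        The score test's p-value is invariant to positive rescaling of K;
        normalization only aids comparability of Q across kernels.
        """
        tr = np.trace(self.values)
        if tr <= 0:
            raise ValueError("cannot normalize a zero kernel")
        return KernelMatrix(
            self.values * (self.n / tr), self.kind, self.level, self.repaired_network
        )


def _check_genotypes(G) -> np.ndarray:
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[1] == 0:
        raise ValueError("genotype matrix must be n x s with s >= 1")
    return G


def linear_kernel(genotypes, level: str = "subject") -> KernelMatrix:
    """``K = G G^T``: additive, independent SNP contributions."""
    G = _check_genotypes(genotypes)
    return KernelMatrix(G @ G.T, "linear", level)


def quadratic_kernel(
    genotypes, offset: float = 1.0, degree: int = 2, level: str = "subject"
) -> KernelMatrix:
    """Polynomial kernel ``K_ij = (offset + g_i^T g_j)^degree``.

    With the default offset 1 and degree 2 this models additive effects plus
    all pairwise SNP interactions.  PSD for offset >= 0 and integer degree.
    """
    if offset < 0 or degree < 1:
        raise ValueError("offset must be >= 0 and degree >= 1")
    G = _check_genotypes(genotypes)
    return KernelMatrix((offset + G @ G.T) ** degree, "quadratic", level)


@dataclass(frozen=True)
class RepairedAdjacency:
    """PSD-repaired pathway adjacency ``N + shift * I``."""

    values: np.ndarray
    repaired: bool
    shift: float

    def factor(self) -> np.ndarray:
        """Symmetric factor ``L`` with ``N = L L^T`` (eigenvalue square root)."""
        w, V = np.linalg.eigh(self.values)
        w = np.clip(w, 0.0, None)
        return V * np.sqrt(w)


def ensure_psd(network: PathwayNetwork, tol: float = 1e-8) -> RepairedAdjacency:
    """Repair the adjacency ``N`` by the minimal diagonal shift.

    If ``min eig(N) >= -tol`` the matrix is returned unchanged; otherwise
    ``N + (|min eig| + 1e-6) I`` is returned and flagged.  The shift
    preserves the topology (off-diagonal pattern) exactly.
    """
    N = network.adjacency
    w_min = float(np.linalg.eigvalsh(N)[0])
    if w_min >= -tol:
        return RepairedAdjacency(N, False, 0.0)
    shift = abs(w_min) + 1e-6
    logger.info(
        "adjacency of %s repaired: min eigenvalue %.4g, diagonal shift %.4g",
        network.name,
        w_min,
        shift,
    )
    return RepairedAdjacency(N + shift * np.eye(N.shape[0]), True, shift)


def network_factor(
    annotation: AnnotationMap,
    network: PathwayNetwork,
    size_adjust: bool = False,
) -> tuple[np.ndarray, bool]:
    """Right factor ``F = A L`` such that ``K = (G F)(G F)^T``.

    ``L`` is a square root of the PSD-repaired adjacency.  Returns the
    ``s x P`` factor and the repaired flag.  SNPs unmapped to any gene get
    all-zero rows (they drop out of the kernel); they are logged.
    """
    if list(annotation.gene_ids) != list(network.gene_ids):
        raise ValueError("annotation and network gene sets do not match")
    rep = ensure_psd(network)
    A = annotation.weights if size_adjust else annotation.incidence
    n_unmapped = int((~annotation.mapped_snps).sum())
    if n_unmapped:
        logger.info("%d unmapped SNP(s) contribute nothing to the kernel", n_unmapped)
    return A @ rep.factor(), rep.repaired


def network_kernel(
    genotypes,
    annotation: AnnotationMap,
    network: PathwayNetwork,
    size_adjust: bool = False,
    level: str = "subject",
) -> KernelMatrix:
    """Topology-aware kernel ``K = G A N A^T G^T``.

    With ``N = I`` and one SNP per gene this reduces exactly to the linear
    kernel on the mapped SNPs.  ``size_adjust`` switches the annotation to
    its ``1/sqrt(c_g)`` column-scaled form.
    """
    G = _check_genotypes(genotypes)
    if G.shape[1] != len(annotation.snp_ids):
        raise ValueError("genotype columns do not match annotation SNPs")
    F, repaired = network_factor(annotation, network, size_adjust)
    B = G @ F
    kind = "size_adjusted_network" if size_adjust else "network"
    return KernelMatrix(B @ B.T, kind, level, repaired_network=repaired)


def expand_to_observations(
    genotypes,
    subject_index,
    time_values,
    interaction: bool = False,
    kernel: str = "linear",
    annotation: AnnotationMap | None = None,
    network: PathwayNetwork | None = None,
) -> KernelMatrix:
    """Observation-level kernel for longitudinal tests.

    Row ``(i, j)`` of the expanded genotype matrix is ``g_i`` for the main
    effect or ``t_ij * g_i`` for the time interaction; rows for missing
    observations are simply absent.  The requested kernel constructor is
    applied to the expanded matrix, so two observations of the same subject
    have main-effect similarity ``k(g_i, g_i)``.
    """
    G = _check_genotypes(genotypes)
    idx = np.asarray(subject_index, dtype=int)
    t = np.asarray(time_values, dtype=float)
    if idx.shape != t.shape:
        raise ValueError("subject_index and time_values must align")
    if idx.min() < 0 or idx.max() >= G.shape[0]:
        raise ValueError("observation refers to a subject without genotype")
    G_obs = G[idx]
    if interaction:
        G_obs = G_obs * t[:, None]
    if kernel == "linear":
        return linear_kernel(G_obs, level="observation")
    if kernel == "quadratic":
        return quadratic_kernel(G_obs, level="observation")
    if kernel in ("network", "size_adjusted_network"):
        if annotation is None or network is None:
            raise ValueError("network kernels need annotation and network")
        return network_kernel(
            G_obs,
            annotation,
            network,
            size_adjust=(kernel == "size_adjusted_network"),
            level="observation",
        )
    raise ValueError(f"unknown kernel kind {kernel!r}")


def kpca_components(kernel: KernelMatrix | np.ndarray, n_components: int = 2):
    """Top kernel-PCA components, for use as fixed-effect adjustments.

    The kernel is double-centered, eigendecomposed, and the leading
    eigenvectors are scaled by the square root of their eigenvalues.  Sign
    convention: the largest-magnitude entry of each component is positive.
    If the centered kernel has rank below ``n_components`` only the rank
    components are returned, with a warning.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    K = kernel.values if isinstance(kernel, KernelMatrix) else np.asarray(kernel, float)
    n = K.shape[0]
    Kc = K - K.mean(axis=0) - K.mean(axis=1)[:, None] + K.mean()
    w, V = np.linalg.eigh(Kc)
    w, V = w[::-1], V[:, ::-1]
    rank = int((w > max(w[0], 0.0) * 1e-10).sum())
    if rank == 0:
        raise ValueError("centered kernel is zero; no components")
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}", stacklevel=2
        )
        n_components = rank
    comps = V[:, :n_components] * np.sqrt(w[:n_components])
    flip = np.sign(comps[np.abs(comps).argmax(axis=0), np.arange(n_components)])
    return comps * flip
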