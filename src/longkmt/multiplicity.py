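"""Pathway-overlap-aware multiple testing and p-value combination.

Pathways tested jointly usually share genes, so Bonferroni over the raw
pathway count is too strict.  The effective number of independent pathways
``P_eff`` is derived from the eigenvalues of ``W W^T``, where row ``r`` of
``W`` spreads pathway ``r`` uniformly over its member genes
(``w_rg = 1/P_r``): ``P_eff`` is the smallest number of leading eigenvalues
whose cumulative share reaches a threshold ``c`` (default 0.95), and the
adjusted level is ``alpha / P_eff``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

__all__ = ["PathwayCollection", "effective_pathways", "fisher_combine"]


@dataclass
class PathwayCollection:
    """Membership matrix over the union of genes of the tested pathways."""

    names: list[str]
    memberships: list[list[str]]

    def __post_init__(self):
        if not self.memberships:
            raise ValueError("no pathways")
        for name, genes in zip(self.names, self.memberships):
            if not genes:
                raise ValueError(f"pathway {name!r} is empty")

    @property
    def union_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for genes in self.memberships:
            for g in genes:
                seen.setdefault(g, None)
        return list(seen)

    @property
    def W(self) -> np.ndarray:
        genes = {g: j for j, g in enumerate(self.union_genes)}
        W = np.zeros((len(self.memberships), len(genes)))
        for r, members in enumerate(self.memberships):
            for g in set(members):
                W[r, genes[g]] = 1.0 / len(set(members))
        return W


def effective_pathways(membership_lists, c: float = 0.95):
    """(P_eff, alpha_adjusted) from the eigenvalues of W W^T.

    ``membership_lists`` is a list of gene-id lists (or a
    :class:`PathwayCollection`).  ``alpha_adjusted = 0.05 / P_eff``.
    """
    if not 0.0 < c <= 1.0:
        raise ValueError("c must lie in (0, 1]")
    if isinstance(membership_lists, PathwayCollection):
        coll = membership_lists
    else:
        coll = PathwayCollection(
            [f"pw{r + 1}" for r in range(len(membership_lists))],
            [list(m) for m in membership_lists],
        )
    W = coll.W
    lam = np.linalg.eigvalsh(W @ W.T)[::-1]
    total = lam.sum()
    share = np.cumsum(lam) / total
    p_eff = int(np.searchsorted(share, c - 1e-12) + 1)
    return p_eff, 0.05 / p_eff


def fisher_combine(p_values) -> float:
    """Fisher's combination: ``-2 sum log p ~ chi2(2k)`` upper tail."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    stat = -2.0 * np.log(p).sum()
    return float(chi2.sf(stat, 2 * p.size))
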