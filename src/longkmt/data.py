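"""Shared genotype container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenotypeMatrix"]


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs dosage matrix with SNP metadata.

    ``values`` holds allele dosages in [0, 2]; ``gene_index`` optionally
    assigns each SNP to a (pseudo-)gene; ``subject_ids`` allow explicit row
    alignment with phenotype tables.
    """

    values: np.ndarray
    snp_ids: list[str]
    positions: np.ndarray | None = None
    chromosome: np.ndarray | None = None
    gene_index: np.ndarray | None = None
    subject_ids: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (subjects x SNPs)")
        if self.values.shape[1] != len(self.snp_ids):
            raise ValueError("snp_ids do not match genotype columns")
        if np.nanmin(self.values) < 0 or np.nanmax(self.values) > 2:
            raise ValueError("dosages must lie in [0, 2]")
        if self.subject_ids is None:
            self.subject_ids = np.arange(self.values.shape[0])
        else:
            self.subject_ids = np.asarray(self.subject_ids)
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.gene_index is not None:
            self.gene_index = np.asarray(self.gene_index, dtype=int)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def maf(self) -> np.ndarray:
        """Sample minor-allele frequency per SNP (folded at 0.5)."""
        f = self.values.mean(axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def rows_for(self, subject_ids) -> np.ndarray:
        """Dosage rows for the requested subjects, in the requested order."""
        index = {s: i for i, s in enumerate(self.subject_ids)}
        try:
            rows = [index[s] for s in subject_ids]
        except KeyError as exc:
            raise KeyError(f"subject {exc.args[0]!r} has no genotype") from None
        return self.values[rows]

    def gene_columns(self, gene: int) -> np.ndarray:
        if self.gene_index is None:
            raise ValueError("no gene assignment stored")
        return np.flatnonzero(self.gene_index == gene)
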