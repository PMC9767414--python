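"""File formats: genotypes, phenotypes, gene sets, networks, coordinates.

Conventions
-----------
* PLINK ``.raw``: whitespace-separated, header ``FID IID PAT MAT SEX
  PHENOTYPE`` then ``SNP_allele`` columns with dosages 0/1/2 or NA.
* dosage TSV: first column subject id, remaining columns one SNP each.
* phenotype TSV: columns ``subject_id``, ``time``, ``y``, then covariates;
  missing y encoded as empty/NA.
* GMT: tab-separated ``set-name <tab> description <tab> gene ...``.
* SIF: ``geneA <tab> interaction <tab> geneB`` (or two columns, no type).
* BED: 0-based half-open intervals, converted to 1-based inclusive
  coordinates internally.
* Missing dosages are mean-imputed per SNP, with a loud log line.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import GenotypeMatrix
from .longitudinal import LongitudinalDataset
from .pathway import GeneCoordinates

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_gmt",
    "read_sif",
    "read_bed",
    "write_kernel",
    "read_kernel",
    "write_results",
    "write_qq_data",
]


def _impute_column_means(values: np.ndarray) -> np.ndarray:
    nan_count = int(np.isnan(values).sum())
    if nan_count:
        means = np.nanmean(values, axis=0)
        idx = np.where(np.isnan(values))
        values[idx] = means[idx[1]]
        logger.warning("mean-imputed %d missing dosage value(s)", nan_count)
    return values


def read_genotypes(path, format: str = "plink_raw") -> GenotypeMatrix:
    """Read a dosage matrix from PLINK .raw or a plain dosage TSV."""
    if format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+")
        meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        if list(df.columns[: len(meta)]) != meta:
            raise ValueError(
                f"{path}: malformed PLINK .raw header "
                f"(expected {' '.join(meta)} ...)"
            )
        snp_cols = list(df.columns[len(meta):])
        subject_ids = df["IID"].to_numpy()
        body = df[snp_cols]
        # strip the _allele suffix PLINK appends to SNP ids
        snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    elif format == "dosage_tsv":
        df = pd.read_csv(path, sep="\t")
        subject_ids = df.iloc[:, 0].to_numpy()
        body = df.iloc[:, 1:]
        snp_ids = list(body.columns)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    try:
        values = body.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError):
        for i, (_, row) in enumerate(body.iterrows()):
            try:
                row.astype(float)
            except (ValueError, TypeError):
                raise ValueError(
                    f"{path}: non-numeric dosage on data line {i + 1}"
                ) from None
        raise
    values = _impute_column_means(values)
    return GenotypeMatrix(values=values, snp_ids=snp_ids, subject_ids=subject_ids)


def write_dosage_tsv(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(gm.values, columns=gm.snp_ids)
    df.insert(0, "subject_id", gm.subject_ids)
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path, covariates=None) -> LongitudinalDataset:
    """Long-format phenotype TSV; covariates default to all extra columns."""
    df = pd.read_csv(path, sep="\t")
    required = ["subject_id", "time", "y"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if covariates is None:
        covariates = [c for c in df.columns if c not in required]
    return LongitudinalDataset(df, covariates=list(covariates))


def write_phenotypes(dataset: LongitudinalDataset, path) -> None:
    dataset.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_gmt(path) -> dict[str, list[str]]:
    """Gene sets: {set name: [gene ids]} (description column ignored)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets[parts[0]] = [g for g in parts[2:] if g]
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_sif(path) -> list[tuple]:
    """Edge records (geneA, geneB[, type]) from SIF or 2-column edge lists."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2:
                records.append((parts[0], parts[1]))
            elif len(parts) == 3:
                records.append((parts[0], parts[2], parts[1]))
            else:
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns")
    return records


def write_sif(edges, path) -> None:
    with open(path, "w") as fh:
        for e in edges:
            a, b = sorted(e)
            fh.write(f"{a}\tinteracts\t{b}\n")


def read_bed(path) -> list[GeneCoordinates]:
    """Gene coordinates from BED (0-based half-open -> 1-based inclusive)."""
    out = []
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError(f"{path}: BED needs chrom, start, end, name columns")
    for _, row in df.iterrows():
        out.append(
            GeneCoordinates(
                gene_id=str(row[3]),
                chromosome=str(row[0]),
                start=int(row[1]) + 1,
                end=int(row[2]),
            )
        )
    return out


def write_kernel(kernel_values: np.ndarray, ids, path) -> None:
    """Square kernel matrix as TSV with an id header (debug/cross-checks)."""
    pd.DataFrame(np.asarray(kernel_values), columns=list(ids)).to_csv(
        path, sep="\t", index=False
    )


def read_kernel(path):
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), list(df.columns)


def write_results(results, path) -> None:
    """Score-test results TSV (one row per pathway x kernel x effect)."""
    rows = []
    for name, res in results:
        rows.append(
            {
                "pathway": name,
                "kernel": res.kernel,
                "effect": res.effect,
                "n_snps": res.n_snps,
                "n_genes": res.n_genes,
                "n_subjects": res.n_subjects,
                "Q": res.Q,
                "p_value": res.p_value,
                "pvalue_method": res.pvalue_method,
                "repaired_network": res.repaired_network,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_qq_data(p_values, path) -> None:
    """(expected, observed) -log10 p pairs for QQ plotting elsewhere."""
    p = np.sort(np.asarray(p_values, dtype=float))
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(np.clip(p, 1e-300, 1.0))
    pd.DataFrame({"expected": expected, "observed": observed}).to_csv(
        path, sep="\t", index=False
    )
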