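"""Readers and writers for the plain-text formats the pipeline exchanges.

Genotypes travel either as the PLINK ``--recode A`` RAW dialect (whitespace
separated, header ``FID IID PAT MAT SEX PHENOTYPE`` followed by one column
per SNP with 0/1/2/NA allele counts) or as a plain CSV with animals in rows
and SNPs in columns. Pedigrees, phenotypes and relationship matrices are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, PedigreeTable

RAW_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]

__all__ = [
    "read_raw",
    "write_raw",
    "read_genotype_csv",
    "write_genotype_csv",
    "read_pedigree_csv",
    "write_pedigree_csv",
    "read_matrix_csv",
    "write_matrix_csv",
    "write_json",
    "read_json",
]


def read_raw(path: str | Path) -> GenotypeMatrix:
    """Read a PLINK RAW-dialect genotype file."""
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    missing = [c for c in RAW_META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"not a RAW file: missing columns {missing}")
    snp_cols = [c for c in df.columns if c not in RAW_META_COLS]
    # PLINK suffixes SNP names with the counted allele (snp_A); strip it.
    snp_ids = [c.rsplit("_", 1)[0] if c.endswith(("_A", "_B")) else c for c in snp_cols]
    return GenotypeMatrix(df[snp_cols].to_numpy(float), df["IID"].astype(str).tolist(), snp_ids)


def write_raw(geno: GenotypeMatrix, path: str | Path, ped: PedigreeTable | None = None) -> None:
    pat = {a: "0" for a in geno.animal_ids}
    mat = dict(pat)
    if ped is not None:
        for a, s, d in ped.table.itertuples(index=False):
            pat[a], mat[a] = s, d
    meta = pd.DataFrame(
        {
            "FID": geno.animal_ids,
            "IID": geno.animal_ids,
            "PAT": [pat.get(a, "0") for a in geno.animal_ids],
            "MAT": [mat.get(a, "0") for a in geno.animal_ids],
            "SEX": 0,
            "PHENOTYPE": -9,
        }
    )
    body = pd.DataFrame(geno.counts, columns=[f"{s}_A" for s in geno.snp_ids])
    out = pd.concat([meta, body.map(lambda v: "NA" if np.isnan(v) else str(int(v)))], axis=1)
    out.to_csv(path, sep=" ", index=False)


def read_genotype_csv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    return GenotypeMatrix(df.to_numpy(float), df.index.astype(str).tolist(), list(df.columns))


def write_genotype_csv(geno: GenotypeMatrix, path: str | Path) -> None:
    geno.to_frame().to_csv(path, index_label="animal")


def read_pedigree_csv(path: str | Path) -> PedigreeTable:
    return PedigreeTable(pd.read_csv(path, dtype=str))


def write_pedigree_csv(ped: PedigreeTable, path: str | Path) -> None:
    ped.table.to_csv(path, index=False)


def read_matrix_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(float), df.index.astype(str).tolist()


def write_matrix_csv(values: np.ndarray, ids: list[str], path: str | Path) -> None:
    pd.DataFrame(values, index=ids, columns=ids).to_csv(path, index_label="animal")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    raise TypeError(f"not JSON serializable: {type(value)}")
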