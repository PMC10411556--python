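"""Plain-text I/O: genotype/phenotype tables, kernels, fitted SVR models.

All formats are TSV/CSV so they interoperate with R/Julia tooling:
genotypes as individuals x SNPs with an id column (missing = NA), or the
PLINK RAW dialect (FID IID PAT MAT SEX PHENOTYPE then dosage columns);
phenotypes as id, generation, one column per trait plus optional
``rel_*`` and ``tbv_*`` columns; kernels/distances as square tables with
id header row and column. Fitted SVR duals serialize to JSON (training
ids, net multipliers, bias, hyperparameters) — enough to re-predict
without refitting.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import GenotypeMatrix, PhenotypeTable

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "write_plink_raw",
    "read_plink_raw",
    "write_phenotypes",
    "read_phenotypes",
    "write_matrix",
    "read_matrix",
    "save_svr_solution",
    "load_svr_solution",
]


def write_genotypes(G: GenotypeMatrix, path, sep: str = ",") -> None:
    vals = G.values.astype(object)
    vals[G.missing_mask] = pd.NA
    df = pd.DataFrame(vals, columns=G.snp_ids)
    df.insert(0, "id", G.ids)
    df.to_csv(path, sep=sep, index=False)


def read_genotypes(path, sep: str | None = None) -> GenotypeMatrix:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    ids = df.iloc[:, 0].astype(str).to_numpy()
    snp_ids = df.columns[1:].to_numpy()
    raw = df.iloc[:, 1:].to_numpy(dtype=float)
    missing = ~np.isfinite(raw)
    values = np.where(missing, 0, raw).astype(np.int8)
    return GenotypeMatrix(values, missing, ids, snp_ids)


def write_plink_raw(G: GenotypeMatrix, path) -> None:
    vals = G.values.astype(object)
    vals[G.missing_mask] = "NA"
    with open(path, "w") as fh:
        fh.write("FID IID PAT MAT SEX PHENOTYPE ")
        fh.write(" ".join(f"{s}_A" for s in G.snp_ids) + "\n")
        for i, iid in enumerate(G.ids):
            row = " ".join(str(v) for v in vals[i])
            fh.write(f"0 {iid} 0 0 0 -9 {row}\n")


def read_plink_raw(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+")
    ids = df["IID"].astype(str).to_numpy()
    snp_cols = df.columns[6:]
    snp_ids = np.array([c[:-2] if c.endswith("_A") else c for c in snp_cols])
    raw = df[snp_cols].to_numpy(dtype=float)
    missing = ~np.isfinite(raw)
    values = np.where(missing, 0, raw).astype(np.int8)
    return GenotypeMatrix(values, missing, ids, snp_ids)


def write_phenotypes(P: PhenotypeTable, path, sep: str = ",") -> None:
    P.to_dataframe().to_csv(path, sep=sep, index=False)


def read_phenotypes(path, sep: str | None = None) -> PhenotypeTable:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    trait_names = [
        c
        for c in df.columns
        if c not in ("id", "generation") and not c.startswith(("rel_", "tbv_"))
    ]
    rel_cols = [f"rel_{n}" for n in trait_names]
    tbv_cols = [f"tbv_{n}" for n in trait_names]
    return PhenotypeTable(
        ids=df["id"].astype(str).to_numpy(),
        generation=df["generation"].to_numpy(),
        trait_values=df[trait_names].to_numpy(dtype=float),
        trait_names=trait_names,
        reliabilities=df[rel_cols].to_numpy(dtype=float)
        if all(c in df.columns for c in rel_cols)
        else None,
        true_breeding_values=df[tbv_cols].to_numpy(dtype=float)
        if all(c in df.columns for c in tbv_cols)
        else None,
    )


def write_matrix(values: np.ndarray, ids, path) -> None:
    pd.DataFrame(values, index=ids, columns=ids).to_csv(path, sep="\t")


def read_matrix(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), df.index.astype(str).to_numpy()


def save_svr_solution(path, train_ids, beta_dual, b0, params: dict) -> None:
    payload = {
        "train_ids": [str(i) for i in train_ids],
        "beta_dual": np.asarray(beta_dual, dtype=float).tolist(),
        "b0": float(b0),
        "params": {
            k: (np.asarray(v).tolist() if isinstance(v, np.ndarray) else v)
            for k, v in params.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_svr_solution(path) -> dict:
    payload = json.loads(Path(path).read_text())
    payload["beta_dual"] = np.asarray(payload["beta_dual"], dtype=float)
    return payload
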