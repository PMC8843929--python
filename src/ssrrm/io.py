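"""Text readers/writers for pedigrees, genotypes, phenotypes and matrices.

Everything is plain delimited text (tab-separated unless noted) so run
artifacts diff cleanly.  Missing parents are encoded 0.  Genotypes are an
0/1/2 matrix with a header row of SNP ids; the PLINK ``--recode A`` "raw"
dialect is accepted on read.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .relmat import Pedigree, GenotypeMatrix, RelationshipMatrix
from .mixedmodel import VarianceComponents

FLOAT_FMT = "%.10g"

__all__ = [
    "write_pedigree", "read_pedigree",
    "write_genotypes", "read_genotypes",
    "write_table", "read_table",
    "write_sparse_matrix", "read_sparse_matrix",
    "write_dense_matrix",
    "write_varcomp", "read_varcomp",
]


def write_pedigree(ped: Pedigree, path) -> None:
    t = ped.table.copy()
    t["birth_date"] = pd.to_datetime(t["birth_date"]).dt.strftime("%Y-%m-%d")
    t["genotyped"] = t["genotyped"].astype(int)
    t.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> Pedigree:
    t = pd.read_csv(path, sep="\t")
    t["birth_date"] = pd.to_datetime(t["birth_date"])
    if "genotyped" in t.columns:
        t["genotyped"] = t["genotyped"].astype(bool)
    else:
        t["genotyped"] = False
    if "litter" not in t.columns:
        t["litter"] = np.arange(1, len(t) + 1)
    return Pedigree(t)


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(geno.matrix, columns=geno.snp_ids)
    df.insert(0, "id", geno.ids)
    df.to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=None, engine="python")
    cols = [c.upper() for c in df.columns[:2]]
    if cols[:2] == ["FID", "IID"]:  # PLINK --recode A raw file
        meta = {"FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"}
        snp_cols = [c for c in df.columns if c.upper() not in meta]
        ids = df["IID"].to_numpy()
        M = df[snp_cols].to_numpy(dtype=float)
        snp_ids = np.array([c.rsplit("_", 1)[0] for c in snp_cols])
    else:
        ids = df.iloc[:, 0].to_numpy()
        snp_ids = np.array(df.columns[1:])
        M = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.isnan(M).any():
        raise ValueError("missing genotypes are not supported; impute first")
    return GenotypeMatrix(ids, snp_ids, M.astype(np.int8))


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sparse_matrix(rm: RelationshipMatrix, path) -> None:
    """Coordinate-format text: header line of ids, then i<TAB>j<TAB>value."""
    m = sp.coo_matrix(rm.matrix)
    with open(path, "w") as fh:
        fh.write("# kind=%s\n" % rm.kind)
        fh.write("# ids=%s\n" % ",".join(map(str, rm.ids)))
        for i, j, v in zip(m.row, m.col, m.data):
            fh.write(f"{i}\t{j}\t{FLOAT_FMT % v}\n")


def read_sparse_matrix(path) -> RelationshipMatrix:
    kind, ids = "A_inv", None
    rows, cols, vals = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                if key.strip() == "kind":
                    kind = val
                elif key.strip() == "ids":
                    ids = np.array([int(x) for x in val.split(",")])
                continue
            i, j, v = line.split()
            rows.append(int(i))
            cols.append(int(j))
            vals.append(float(v))
    n = len(ids)
    m = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return RelationshipMatrix(ids, m, kind)


def write_dense_matrix(rm: RelationshipMatrix, path) -> None:
    df = pd.DataFrame(rm.dense(), index=rm.ids, columns=rm.ids)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def write_varcomp(vc: VarianceComponents, path, meta: dict | None = None) -> None:
    obj = {
        "covs": {k: np.asarray(v).tolist() for k, v in vc.covs.items()},
        "sigma2_e": vc.sigma2_e,
        "loglik": vc.loglik,
        "converged": vc.converged,
        "n_iter": vc.n_iter,
        "meta": meta or {},
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def read_varcomp(path) -> VarianceComponents:
    with open(path) as fh:
        obj = json.load(fh)
    return VarianceComponents({k: np.array(v) for k, v in obj["covs"].items()},
                              obj["sigma2_e"], loglik=obj["loglik"],
                              converged=obj["converged"], n_iter=obj["n_iter"])
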