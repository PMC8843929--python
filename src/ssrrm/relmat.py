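"""Relationship matrices for pedigree and genomic evaluation.

Builds the numerator relationship matrix ``A`` (tabular method with
inbreeding), its sparse inverse via Henderson's rules with inbreeding
coefficients from the Meuwissen & Luo recursion, the VanRaden (method 1)
genomic relationship matrix ``G``, and the single-step inverse

    H^-1 = A^-1 + [0 0; 0 tau*(alpha*G + beta*A22)^-1 - omega*A22^-1]

applied on the genotyped block only, with defaults
(alpha, beta, tau, omega) = (0.95, 0.05, 1.00, 1.00).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.linalg as la

__all__ = [
    "Pedigree",
    "GenotypeMatrix",
    "RelationshipMatrix",
    "HBlendParams",
    "inbreeding",
    "build_A",
    "build_A_inverse",
    "build_G",
    "subset_A",
    "blend_G",
    "build_H_inverse",
]


@dataclass
class Pedigree:
    """Topologically ordered pedigree (parents precede offspring).

    ``table`` columns: id, sire, dam (0 = unknown), birth_date, litter,
    sex, genotyped, generation.  Ids are positive integers.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"id", "sire", "dam"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"pedigree table missing columns: {sorted(missing)}")
        ids = t["id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("duplicate animal ids in pedigree")
        pos = {a: i for i, a in enumerate(ids)}
        for col in ("sire", "dam"):
            for a, p in zip(ids, t[col].to_numpy()):
                if p != 0:
                    if p not in pos:
                        raise ValueError(f"unknown {col} id {p} for animal {a}")
                    if pos[p] >= pos[a]:
                        raise ValueError(
                            f"animal {a} listed before its {col} {p}; pedigree must be ordered"
                        )
        self._pos = pos

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    @property
    def n(self) -> int:
        return len(self.table)

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """0-based sire/dam indices, -1 for unknown."""
        pos = self._pos
        sire = np.array([pos.get(s, -1) if s != 0 else -1 for s in self.table["sire"]])
        dam = np.array([pos.get(d, -1) if d != 0 else -1 for d in self.table["dam"]])
        return sire, dam

    def index_of(self, ids) -> np.ndarray:
        return np.array([self._pos[a] for a in np.atleast_1d(ids)])

    @property
    def genotyped_ids(self) -> np.ndarray:
        if "genotyped" not in self.table.columns:
            return np.array([], dtype=self.ids.dtype)
        return self.table.loc[self.table["genotyped"].astype(bool), "id"].to_numpy()


@dataclass
class GenotypeMatrix:
    """SNP genotypes coded 0/1/2 (counts of the alternative allele)."""

    ids: np.ndarray
    snp_ids: np.ndarray
    matrix: np.ndarray  # (n_animals, n_snps), int

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.snp_ids = np.asarray(self.snp_ids)
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError("genotype matrix shape does not match id lists")
        if self.matrix.size and not np.isin(self.matrix, (0, 1, 2)).all():
            raise ValueError("genotypes must be coded 0/1/2")

    @property
    def allele_freq(self) -> np.ndarray:
        return self.matrix.mean(axis=0) / 2.0


@dataclass
class RelationshipMatrix:
    """Square symmetric relationship matrix keyed by an ordered id list."""

    ids: np.ndarray
    matrix: np.ndarray | sp.spmatrix
    kind: str  # A | A_inv | G | G_blend | H_inv | A22
    logdet: float | None = field(default=None)  # log|R| of the *relationship* R

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("relationship matrix shape does not match id list")

    def dense(self) -> np.ndarray:
        m = self.matrix
        return m.toarray() if sp.issparse(m) else np.asarray(m)

    def check_symmetric(self, tol: float = 1e-8) -> None:
        d = self.dense()
        scale = max(1.0, float(np.abs(d).max()))
        if np.abs(d - d.T).max() > tol * scale:
            raise ValueError(f"{self.kind} matrix is not symmetric")


@dataclass
class HBlendParams:
    """Blending scalars of the single-step genotyped-block correction."""

    alpha: float = 0.95
    beta: float = 0.05
    tau: float = 1.0
    omega: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "tau", "omega"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def inbreeding(ped: Pedigree) -> tuple[np.ndarray, np.ndarray]:
    """Inbreeding coefficients F and within-family variances d (Meuwissen & Luo).

    d_i is the Mendelian-sampling variance scale:
    1 (no parents), 0.75 - F_p/4 (one parent), 0.5 - (F_s + F_d)/4 (both).
    Also gives log|A| = sum(log d) cheaply.
    """
    sire, dam = ped.parent_indices()
    n = ped.n
    F = np.zeros(n)
    d = np.empty(n)
    for i in range(n):
        s, dm = sire[i], dam[i]
        fs = F[s] if s >= 0 else -1.0
        fd = F[dm] if dm >= 0 else -1.0
        d[i] = 0.5 - 0.25 * (fs + fd)
        if s < 0 or dm < 0:
            # F = 0 unless both parents known
            continue
        # a_ii = sum_j L_ij^2 d_j over the ancestors of i
        coeff: dict[int, float] = {i: 1.0}
        aii = 0.0
        for j in range(i, -1, -1):
            cj = coeff.pop(j, 0.0)
            if cj == 0.0:
                continue
            aii += cj * cj * d[j]
            if sire[j] >= 0:
                coeff[sire[j]] = coeff.get(sire[j], 0.0) + 0.5 * cj
            if dam[j] >= 0:
                coeff[dam[j]] = coeff.get(dam[j], 0.0) + 0.5 * cj
        F[i] = aii - 1.0
        # d was provisional for animal i itself only via parents; recompute not needed
    return F, d


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method (with inbreeding)."""
    sire, dam = ped.parent_indices()
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, dm = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if dm >= 0:
            row += 0.5 * A[dm, :i]
        A[i, :i] = row
        A[:i, i] = row
        asd = A[s, dm] if (s >= 0 and dm >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
    F, d = inbreeding(ped)
    return RelationshipMatrix(ped.ids, A, "A", logdet=float(np.log(d).sum()))


def build_A_inverse(ped: Pedigree) -> RelationshipMatrix:
    """Sparse A^-1 by Henderson's rules with Meuwissen-Luo inbreeding."""
    sire, dam = ped.parent_indices()
    _, d = inbreeding(ped)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(ped.n):
        alpha = 1.0 / d[i]
        parents = [p for p in (sire[i], dam[i]) if p >= 0]
        add(i, i, alpha)
        for p in parents:
            add(i, p, -alpha / 2.0)
            add(p, i, -alpha / 2.0)
            add(p, p, alpha / 4.0)
        if len(parents) == 2:
            s, dm = parents
            add(s, dm, alpha / 4.0)
            add(dm, s, alpha / 4.0)
    Ainv = sp.csr_matrix((vals, (rows, cols)), shape=(ped.n, ped.n))
    return RelationshipMatrix(ped.ids, Ainv, "A_inv", logdet=float(np.log(d).sum()))


def build_G(geno: GenotypeMatrix, allele_freq: np.ndarray | None = None) -> RelationshipMatrix:
    """Genomic relationship matrix, VanRaden method 1.

    Z = M - 2p with p the (observed, by default) allele frequencies;
    G = Z Z' / (2 * sum p_j (1 - p_j)).  Monomorphic SNPs contribute
    nothing to numerator or denominator.
    """
    M = geno.matrix.astype(float)
    if M.size == 0:
        raise ValueError("empty genotype matrix")
    p = geno.allele_freq if allele_freq is None else np.asarray(allele_freq, dtype=float)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic; G undefined")
    Z = M - 2.0 * p
    denom = 2.0 * float((p[poly] * (1.0 - p[poly])).sum())
    G = (Z @ Z.T) / denom
    return RelationshipMatrix(geno.ids, G, "G")


def subset_A(A: RelationshipMatrix, ids) -> RelationshipMatrix:
    """A22: sub-block of a dense A for the given (ordered) id list."""
    pos = {a: i for i, a in enumerate(A.ids)}
    idx = np.array([pos[a] for a in ids])
    sub = A.dense()[np.ix_(idx, idx)]
    return RelationshipMatrix(np.asarray(ids), sub, "A22")


def blend_G(G: RelationshipMatrix, A22: RelationshipMatrix,
            params: HBlendParams | None = None) -> RelationshipMatrix:
    """alpha*G + beta*A22 on a shared ordered genotyped-id list."""
    params = params or HBlendParams()
    if len(G.ids) != len(A22.ids) or (G.ids != A22.ids).any():
        raise ValueError("G and A22 must be keyed by identical ordered id lists")
    Gb = params.alpha * G.dense() + params.beta * A22.dense()
    return RelationshipMatrix(G.ids, Gb, "G_blend")


def build_H_inverse(A_inv: RelationshipMatrix, A22: RelationshipMatrix,
                    G_blend: RelationshipMatrix, params: HBlendParams,
                    genotyped_ids) -> RelationshipMatrix:
    """Single-step H^-1 in the caller's pedigree ordering.

    Adds tau*(alpha G + beta A22)^-1 - omega*A22^-1 on the genotyped block
    of A^-1.  Internally the genotyped animals are addressed by index into
    the full id list; no reordering of the output is needed.
    """
    genotyped_ids = np.asarray(genotyped_ids)
    if len(genotyped_ids) == 0:
        return RelationshipMatrix(A_inv.ids, A_inv.matrix.copy(), "H_inv",
                                  logdet=A_inv.logdet)
    pos = {a: i for i, a in enumerate(A_inv.ids)}
    if not all(a in pos for a in genotyped_ids):
        raise ValueError("genotyped ids must be a subset of pedigree ids")
    if (np.asarray(G_blend.ids) != genotyped_ids).any() or (np.asarray(A22.ids) != genotyped_ids).any():
        raise ValueError("G_blend/A22 id order must match genotyped_ids")
    idx = np.array([pos[a] for a in genotyped_ids])

    try:
        c, low = la.cho_factor(G_blend.dense())
        Gb_inv = la.cho_solve((c, low), np.eye(len(idx)))
    except la.LinAlgError as e:
        raise np.linalg.LinAlgError(f"blended G is singular: {e}") from e
    try:
        c, low = la.cho_factor(A22.dense())
        A22_inv = la.cho_solve((c, low), np.eye(len(idx)))
    except la.LinAlgError as e:
        raise np.linalg.LinAlgError(f"A22 is singular: {e}") from e

    corr = params.tau * Gb_inv - params.omega * A22_inv
    corr = 0.5 * (corr + corr.T)
    block = sp.coo_matrix(
        (corr.ravel(), (np.repeat(idx, len(idx)), np.tile(idx, len(idx)))),
        shape=A_inv.matrix.shape,
    )
    Hinv = (sp.csr_matrix(A_inv.matrix) + block.tocsr())
    return RelationshipMatrix(A_inv.ids, Hinv, "H_inv")
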