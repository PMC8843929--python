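"""Mixed-model machinery: design matrices, Henderson's MME, REML, BIC.

Two model kinds are supported on the same machinery:

* ``animal`` — one record per animal (average daily feed intake), random
  additive and litter intercepts;
* ``rrm`` — a random-regression test-day model on daily feed intake, with
  normalised Legendre polynomials of standardised age as the covariance
  function basis for additive, permanent-environment and litter curves,
  and a time-independent homogeneous residual.

Both share the fixed part: year-season, pen, and the four energy-sink
covariates (ADG, back fat, start weight, metabolic weight) whose
regressions turn feed intake into residual feed intake.

Variance components are estimated by EM-REML with average-information
acceleration; the restricted likelihood is evaluated through the mixed
model equations, so the same coefficient matrix serves estimation,
prediction and PEV extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .relmat import RelationshipMatrix

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "RandomTerm",
    "DesignBundle",
    "MMESystem",
    "legendre_basis",
    "legendre_matrix",
    "build_design_matrices",
    "assemble_and_solve_mme",
    "reml_estimate",
    "compute_bic",
    "n_free_parameters",
    "select_model_order",
]

COVARIATES = ("adg", "bfa", "sbw", "mbw")


# ---------------------------------------------------------------------------
# Legendre basis

def legendre_matrix(ages, t_min: float, t_max: float, order: int) -> np.ndarray:
    """Normalised Legendre basis rows phi_m(t*) for a vector of ages.

    t* = 2(t - t_min)/(t_max - t_min) - 1; phi_m = sqrt((2m+1)/2) P_m(t*),
    orthonormal on [-1, 1].
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    if (ages < t_min - 1e-9).any() or (ages > t_max + 1e-9).any():
        raise ValueError("age outside the standardisation bounds")
    x = 2.0 * (ages - t_min) / (t_max - t_min) - 1.0
    V = np.polynomial.legendre.legvander(x, order)
    norm = np.sqrt((2.0 * np.arange(order + 1) + 1.0) / 2.0)
    return V * norm


def legendre_basis(age: float, t_min: float, t_max: float, order: int) -> np.ndarray:
    """phi(t) at a single age (see :func:`legendre_matrix`)."""
    return legendre_matrix([age], t_min, t_max, order)[0]


# ---------------------------------------------------------------------------
# Specifications and variance components

@dataclass
class ModelSpec:
    """Model kind and curve orders.

    For ``rrm``: p/q/n are the Legendre orders of the additive,
    permanent-environment and litter curves (the selected configuration is
    p=2, q=1, n=1).  ``animal`` ignores the orders (scalar effects) and has
    no permanent-environment term.  t_min/t_max are the age-standardisation
    bounds stored with the model so basis evaluation is reproducible.
    """

    kind: str = "rrm"
    p: int = 2
    q: int = 1
    n: int = 1
    t_min: float = 99.0
    t_max: float = 172.0
    covariates: tuple[str, ...] = COVARIATES

    def __post_init__(self) -> None:
        if self.kind not in ("animal", "rrm"):
            raise ValueError("kind must be 'animal' or 'rrm'")
        if min(self.p, self.q, self.n) < 0:
            raise ValueError("Legendre orders must be >= 0")
        if self.t_min >= self.t_max:
            raise ValueError("t_min must be < t_max")

    @property
    def term_orders(self) -> dict[str, int]:
        if self.kind == "animal":
            return {"litter": 0, "additive": 0}
        return {"litter": self.n, "additive": self.p, "pe": self.q}

    def basis(self, ages, term: str) -> np.ndarray:
        if self.kind == "animal":
            return np.ones((len(np.atleast_1d(ages)), 1))
        return legendre_matrix(ages, self.t_min, self.t_max, self.term_orders[term])


@dataclass
class VarianceComponents:
    """(Co)variance components: one k x k matrix per random term + residual."""

    covs: dict[str, np.ndarray]
    sigma2_e: float
    loglik: float | None = None
    converged: bool = True
    n_iter: int = 0
    history: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.covs = {k: np.atleast_2d(np.asarray(v, dtype=float))
                     for k, v in self.covs.items()}
        if self.sigma2_e < 0:
            raise ValueError("residual variance must be >= 0")
        for name, K in self.covs.items():
            if np.linalg.eigvalsh(K).min() < -1e-8 * max(np.trace(K), 1.0):
                raise ValueError(f"{name} covariance is not positive semidefinite")

    @property
    def sigma2_a(self) -> float:
        return float(self.covs["additive"][0, 0])

    @property
    def sigma2_litter(self) -> float:
        return float(self.covs["litter"][0, 0])


# ---------------------------------------------------------------------------
# Design matrices

@dataclass
class RandomTerm:
    """Incidence structure of one random-curve term."""

    name: str
    level_ids: np.ndarray
    k: int                      # coefficients per level
    Z: sp.csr_matrix            # n_records x (n_levels * k), level-major

    @property
    def n_levels(self) -> int:
        return len(self.level_ids)

    @property
    def width(self) -> int:
        return self.n_levels * self.k


@dataclass
class DesignBundle:
    """Response, fixed design and random incidence matrices for one model."""

    spec: ModelSpec
    y: np.ndarray
    X: np.ndarray
    fixed_names: list[str]
    terms: list[RandomTerm]
    record_animals: np.ndarray
    ages_by_animal: dict[int, np.ndarray]

    @property
    def n_records(self) -> int:
        return len(self.y)

    def term(self, name: str) -> RandomTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def _dummy_code(levels: pd.Series, prefix: str) -> tuple[np.ndarray, list[str]]:
    """Reference-level dummy coding (first sorted level dropped)."""
    cats = np.sort(levels.unique())
    cols, names = [], []
    for c in cats[1:]:
        cols.append((levels.to_numpy() == c).astype(float))
        names.append(f"{prefix}_{c}")
    if cols:
        return np.column_stack(cols), names
    return np.empty((len(levels), 0)), names


def _term_Z(rec_level_idx: np.ndarray, basis_rows: np.ndarray,
            n_levels: int) -> sp.csr_matrix:
    n_rec, k = basis_rows.shape
    rows = np.repeat(np.arange(n_rec), k)
    cols = (rec_level_idx[:, None] * k + np.arange(k)[None, :]).ravel()
    return sp.csr_matrix((basis_rows.ravel(), (rows, cols)),
                         shape=(n_rec, n_levels * k))


def build_design_matrices(spec: ModelSpec, pheno: pd.DataFrame,
                          covars: pd.DataFrame, ped) -> DesignBundle:
    """Assemble X and the random incidence matrices.

    ``pheno`` is the daily long table (rrm) or any per-animal table carrying
    ys/pen (animal kind; the response is then ADFI from ``covars``).  The
    additive term spans *all* pedigree animals so ancestors without records
    receive breeding values through the relationship matrix.
    """
    ped_ids = ped.ids
    known = np.isin(pheno["animal"].unique(), ped_ids)
    if not known.all():
        bad = pheno["animal"].unique()[~known][:5]
        raise ValueError(f"records for animals missing from the pedigree: {bad}")

    if spec.kind == "animal":
        per = (pheno.sort_values(["animal"])
                    .groupby("animal", sort=True)
                    .agg(ys=("ys", "first"), pen=("pen", "first"))
                    .reset_index())
        per = per.merge(covars, on="animal", how="inner", validate="1:1")
        if per.empty:
            raise ValueError("no animals with both phenotype and covariates")
        data = per
        y = data["adfi"].to_numpy(dtype=float)
        rec_animal = data["animal"].to_numpy()
        rec_age = None
    else:
        data = pheno.merge(covars[["animal", *spec.covariates]], on="animal",
                           how="inner", validate="m:1").sort_values(["animal", "age"])
        if data.empty:
            raise ValueError("no records after joining phenotypes and covariates")
        y = data["intake"].to_numpy(dtype=float)
        rec_animal = data["animal"].to_numpy()
        rec_age = data["age"].to_numpy(dtype=float)

    Xys, ys_names = _dummy_code(data["ys"], "ys")
    Xpen, pen_names = _dummy_code(data["pen"], "pen")
    Xcov = data[list(spec.covariates)].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(data)), Xys, Xpen, Xcov])
    fixed_names = ["intercept", *ys_names, *pen_names, *spec.covariates]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient (confounded levels)")

    orders = spec.term_orders
    lit_by_animal = dict(zip(ped.table["id"], ped.table["litter"]))
    rec_litter = np.array([lit_by_animal[a] for a in rec_animal])

    terms: list[RandomTerm] = []

    lit_levels = np.sort(np.unique(rec_litter))
    lit_idx = np.searchsorted(lit_levels, rec_litter)
    basis = spec.basis(rec_age if rec_age is not None else np.zeros(len(data)), "litter")
    terms.append(RandomTerm("litter", lit_levels, orders["litter"] + 1,
                            _term_Z(lit_idx, basis, len(lit_levels))))

    anim_idx = ped.index_of(rec_animal)
    basis = spec.basis(rec_age if rec_age is not None else np.zeros(len(data)), "additive")
    terms.append(RandomTerm("additive", ped_ids, orders["additive"] + 1,
                            _term_Z(anim_idx, basis, len(ped_ids))))

    if spec.kind == "rrm":
        pe_levels = np.sort(np.unique(rec_animal))
        pe_idx = np.searchsorted(pe_levels, rec_animal)
        basis = spec.basis(rec_age, "pe")
        terms.append(RandomTerm("pe", pe_levels, orders["pe"] + 1,
                                _term_Z(pe_idx, basis, len(pe_levels))))

    if rec_age is not None:
        ages_by_animal = {int(a): g["age"].to_numpy(dtype=float)
                          for a, g in data.groupby("animal")}
    else:
        ages_by_animal = {}
    return DesignBundle(spec, y, X, fixed_names, terms, rec_animal, ages_by_animal)


# ---------------------------------------------------------------------------
# Mixed model equations

def _chol_inverse(L: np.ndarray) -> np.ndarray:
    """Inverse of a SPD matrix from its lower Cholesky factor (LAPACK dpotri)."""
    inv, info = la.lapack.dpotri(L, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError(f"dpotri failed with info={info}")
    inv = np.tril(inv) + np.tril(inv, -1).T
    return inv


def _safe_inv(K: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    K = np.atleast_2d(K)
    w, V = np.linalg.eigh(K)
    w = np.maximum(w, floor * max(np.trace(K), floor))
    return (V / w) @ V.T


class MMESystem:
    """Henderson's mixed model equations for one design + variance set.

    C = W' W / sigma2_e + blockdiag(0, kron(Rinv_t, Kinv_t)), rhs = W'y/sigma2_e.
    ``K_inv`` is the pedigree (A^-1) or single-step (H^-1) inverse attached
    to the additive term; other terms use identity relationships.
    """

    def __init__(self, designs: DesignBundle, K_inv: RelationshipMatrix | None,
                 vc: VarianceComponents):
        has_additive = any(t.name == "additive" for t in designs.terms)
        if has_additive:
            if K_inv is None or K_inv.kind not in ("A_inv", "H_inv"):
                raise ValueError("K_inv must be an A_inv or H_inv relationship matrix")
            add = designs.term("additive")
            if len(K_inv.ids) != len(add.level_ids) or (K_inv.ids != add.level_ids).any():
                raise ValueError("K_inv ids must match the pedigree ordering of the additive term")
        self.designs = designs
        self.K_inv = K_inv
        self.vc = vc

        mats = [sp.csr_matrix(designs.X)] + [t.Z for t in designs.terms]
        self.W = sp.hstack(mats, format="csr")
        self.n_fixed = designs.X.shape[1]
        self.blocks: dict[str, slice] = {"fixed": slice(0, self.n_fixed)}
        off = self.n_fixed
        for t in designs.terms:
            self.blocks[t.name] = slice(off, off + t.width)
            off += t.width
        self.n_eq = off

        pen = sp.lil_matrix((self.n_eq, self.n_eq))
        for t in designs.terms:
            Kt = vc.covs[t.name]
            if Kt.shape[0] != t.k:
                raise ValueError(f"variance matrix for '{t.name}' has order "
                                 f"{Kt.shape[0]}, expected {t.k}")
            Kinv_small = _safe_inv(Kt)
            rel = (K_inv.matrix if t.name == "additive"
                   else sp.identity(t.n_levels, format="csr"))
            block = sp.kron(sp.csr_matrix(rel), Kinv_small, format="csr")
            sl = self.blocks[t.name]
            pen[sl, sl] = block
        self.penalty = pen.tocsr()

        self.C = (self.W.T @ self.W) / vc.sigma2_e + self.penalty
        self.rhs = np.asarray(self.W.T @ designs.y).ravel() / vc.sigma2_e
        self._solution: np.ndarray | None = None
        self._lu = None
        self._Cinv: np.ndarray | None = None

    def solve(self) -> np.ndarray:
        if self._solution is None:
            try:
                self._lu = spla.splu(self.C.tocsc())
                self._solution = self._lu.solve(self.rhs)
            except RuntimeError as e:
                raise np.linalg.LinAlgError(
                    f"singular mixed-model equations (check fixed-effect "
                    f"confounding); blocks: {list(self.blocks)}") from e
        return self._solution

    @property
    def solution(self) -> np.ndarray:
        return self.solve()

    def coef(self, name: str) -> np.ndarray:
        """Solutions of one block; random terms reshaped to (levels, k)."""
        sol = self.solve()[self.blocks[name]]
        if name == "fixed":
            return sol
        t = self.designs.term(name)
        return sol.reshape(t.n_levels, t.k)

    def inverse(self) -> np.ndarray:
        """Dense inverse of the coefficient matrix (cached)."""
        if self._Cinv is None:
            C = self.C.toarray()
            try:
                c, low = la.cho_factor(C, lower=True)
            except la.LinAlgError as e:
                raise np.linalg.LinAlgError(f"coefficient matrix not PD: {e}") from e
            self._Cinv = _chol_inverse(np.tril(c))
        return self._Cinv

    def pev_blocks(self, name: str) -> np.ndarray:
        """Per-level k x k prediction-error (co)variance blocks of a term."""
        t = self.designs.term(name)
        Cinv = self.inverse()
        sl = self.blocks[name]
        sub = Cinv[sl, sl]
        out = np.empty((t.n_levels, t.k, t.k))
        for lev in range(t.n_levels):
            s = slice(lev * t.k, (lev + 1) * t.k)
            out[lev] = sub[s, s]
        return out

    def residuals(self) -> np.ndarray:
        return self.designs.y - np.asarray(self.W @ self.solve()).ravel()


def assemble_and_solve_mme(designs: DesignBundle, K_inv: RelationshipMatrix,
                           vc: VarianceComponents) -> MMESystem:
    mme = MMESystem(designs, K_inv, vc)
    mme.solve()
    return mme


# ---------------------------------------------------------------------------
# REML

def _rel_logdet(term: RandomTerm, K_inv: RelationshipMatrix) -> float:
    """log|R| of the relationship matrix of a term (0 for identity)."""
    if term.name != "additive":
        return 0.0
    if K_inv.logdet is not None:
        return float(K_inv.logdet)
    M = K_inv.matrix
    if sp.issparse(M):
        lu = spla.splu(M.tocsc())
        diag = lu.U.diagonal()
        ld = float(np.sum(np.log(np.abs(diag))))
    else:
        ld = float(np.linalg.slogdet(M)[1])
    return -ld  # log|R| = -log|R^-1|


def _init_vc(designs: DesignBundle) -> VarianceComponents:
    """Heuristic start: split the OLS residual variance across terms."""
    X, y = designs.X, designs.y
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    vp = float(np.var(y - X @ beta, ddof=X.shape[1]))
    vp = max(vp, 1e-6)
    shares = {"additive": 0.35, "pe": 0.25, "litter": 0.10}
    covs = {}
    for t in designs.terms:
        share = shares.get(t.name, 0.1)
        # spread over coefficients with geometric decay; the factor 2 undoes
        # the phi_0^2 = 1/2 of the normalised constant term
        diag = 2.0 * share * vp * (0.5 ** np.arange(t.k))
        covs[t.name] = np.diag(diag)
    return VarianceComponents(covs, sigma2_e=0.4 * vp)


class _REMLEngine:
    def __init__(self, designs: DesignBundle, K_inv: RelationshipMatrix | None):
        self.d = designs
        self.K_inv = K_inv
        if any(t.name == "additive" for t in designs.terms):
            if K_inv is None:
                raise ValueError("additive term requires a relationship inverse")
            add = designs.term("additive")
            if len(K_inv.ids) != len(add.level_ids) or (K_inv.ids != add.level_ids).any():
                raise ValueError("K_inv ids must match pedigree ordering")
        mats = [sp.csr_matrix(designs.X)] + [t.Z for t in designs.terms]
        self.W = sp.hstack(mats, format="csr")
        self.WtW = (self.W.T @ self.W).toarray()
        self.Wty = np.asarray(self.W.T @ designs.y).ravel()
        self.yty = float(designs.y @ designs.y)
        self.N = designs.n_records
        self.nf = designs.X.shape[1]
        self.n_eq = self.WtW.shape[0]
        self.blocks: dict[str, slice] = {}
        off = self.nf
        for t in designs.terms:
            self.blocks[t.name] = slice(off, off + t.width)
            off += t.width
        self.rel: dict[str, sp.coo_matrix | None] = {}
        self.rel_logdet: dict[str, float] = {}
        for t in designs.terms:
            if t.name == "additive":
                self.rel[t.name] = sp.coo_matrix(K_inv.matrix)
            else:
                self.rel[t.name] = None  # identity
            self.rel_logdet[t.name] = _rel_logdet(t, K_inv)

    # -- likelihood pieces -------------------------------------------------
    def build_C(self, covs: dict[str, np.ndarray], s2e: float) -> np.ndarray:
        C = self.WtW / s2e
        for t in self.d.terms:
            Kinv = _safe_inv(covs[t.name])
            sl = self.blocks[t.name]
            rel = self.rel[t.name]
            if rel is None:
                # identity relationship: add Kinv on each level's diagonal block
                idx = np.arange(t.n_levels)
                base = sl.start
                for i in range(t.k):
                    for j in range(t.k):
                        C[base + idx * t.k + i, base + idx * t.k + j] += Kinv[i, j]
            else:
                base = sl.start
                r, c, v = rel.row, rel.col, rel.data
                for i in range(t.k):
                    for j in range(t.k):
                        C[base + r * t.k + i, base + c * t.k + j] += v * Kinv[i, j]
        return C

    def loglik_and_chol(self, covs, s2e):
        C = self.build_C(covs, s2e)
        try:
            cfac = la.cho_factor(C, lower=True)
        except la.LinAlgError:
            return -np.inf, None, None, None
        theta = la.cho_solve(cfac, self.Wty / s2e)
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cfac[0]))))
        yPy = self.yty / s2e - float(theta @ self.Wty) / s2e
        m2l = (self.N - self.nf) * np.log(2 * np.pi) + self.N * np.log(s2e) + logdetC + yPy
        for t in self.d.terms:
            K = covs[t.name]
            sign, ldK = np.linalg.slogdet(K)
            if sign <= 0:
                return -np.inf, None, None, None
            m2l += t.k * self.rel_logdet[t.name] + t.n_levels * ldK
        return -0.5 * m2l, C, cfac, theta

    # -- sufficient statistics --------------------------------------------
    def term_stats(self, t: RandomTerm, theta: np.ndarray, Cinv: np.ndarray):
        sl = self.blocks[t.name]
        U = theta[sl].reshape(t.n_levels, t.k)
        rel = self.rel[t.name]
        RU = U if rel is None else np.asarray(rel.tocsr() @ U)
        S = U.T @ RU
        sub = Cinv[sl, sl]
        T = np.empty((t.k, t.k))
        for i in range(t.k):
            for j in range(i, t.k):
                blk = sub[i::t.k, j::t.k]
                if rel is None:
                    T[i, j] = float(np.trace(blk))
                else:
                    T[i, j] = float(rel.data @ blk[rel.col, rel.row])
                T[j, i] = T[i, j]
        return U, S, T


def _pack(covs: dict[str, np.ndarray], s2e: float, terms) -> np.ndarray:
    out = []
    for t in terms:
        K = covs[t.name]
        out.extend(K[i, j] for i in range(t.k) for j in range(i, t.k))
    out.append(s2e)
    return np.array(out)


def _unpack(vec: np.ndarray, terms) -> tuple[dict[str, np.ndarray], float]:
    covs = {}
    pos = 0
    for t in terms:
        K = np.empty((t.k, t.k))
        for i in range(t.k):
            for j in range(i, t.k):
                K[i, j] = K[j, i] = vec[pos]
                pos += 1
        covs[t.name] = K
    return covs, float(vec[pos])


def _project_psd(K: np.ndarray, floor_frac: float = 1e-8) -> np.ndarray:
    w, V = np.linalg.eigh(K)
    floor = floor_frac * max(np.abs(w).max(), 1e-12)
    w = np.maximum(w, floor)
    return (V * w) @ V.T


def reml_estimate(designs: DesignBundle, K_inv: RelationshipMatrix,
                  init: VarianceComponents | None = None, *,
                  algorithm: str = "ai", tol: float = 1e-8,
                  max_iter: int = 500, em_warmup: int = 3,
                  logl_tol: float = 1e-9,
                  verbose: bool = False) -> VarianceComponents:
    """EM-REML with average-information acceleration.

    EM steps are guaranteed to keep the covariance matrices inside the PSD
    cone and the restricted likelihood non-decreasing; AI steps (after
    ``em_warmup`` iterations) are accepted only when they improve the
    likelihood, with step halving and EM fallback otherwise.

    Convergence: maximum relative parameter change < ``tol`` (denominator
    floored at 1e-6 of the phenotypic-variance scale so a component
    collapsing to the boundary of the parameter space cannot stall the
    run), or restricted log-likelihood change < ``logl_tol`` — the latter
    matters when an over-parameterised model drives a covariance matrix
    singular and EM approaches the boundary only geometrically.
    """
    if algorithm not in ("em", "ai"):
        raise ValueError("algorithm must be 'em' or 'ai'")
    eng = _REMLEngine(designs, K_inv)
    terms = designs.terms
    vc = init if init is not None else _init_vc(designs)
    covs = {k: v.copy() for k, v in vc.covs.items()}
    s2e = float(vc.sigma2_e)
    n_par = sum(t.k * (t.k + 1) // 2 for t in terms) + 1
    if designs.n_records <= n_par:
        raise ValueError("fewer records than variance parameters")

    history = []
    converged = False
    logL = -np.inf
    it = 0
    ai_fails = 0
    for it in range(1, max_iter + 1):
        prev_logL = logL
        logL, C, cfac, theta = eng.loglik_and_chol(covs, s2e)
        if not np.isfinite(logL):
            raise FloatingPointError("restricted likelihood not finite; check starting values")
        history.append(logL)
        if it > 1 and abs(logL - prev_logL) < logl_tol:
            converged = True
            break
        Cinv = _chol_inverse(np.tril(cfac[0]))
        stats = {t.name: eng.term_stats(t, theta, Cinv) for t in terms}

        # EM candidate
        em_covs = {}
        for t in terms:
            _, S, T = stats[t.name]
            em_covs[t.name] = _project_psd((S + T) / t.n_levels)
        resid = eng.yty - float(theta @ eng.Wty)
        em_s2e = max(resid / (eng.N - eng.nf), 1e-12)

        new_covs, new_s2e = em_covs, em_s2e
        if algorithm == "ai" and it > em_warmup:
            # after repeated AI rejections (boundary optimum) retry only
            # every third iteration to avoid wasted line searches
            if ai_fails < 2 or it % 3 == 0:
                cand = _ai_step(eng, terms, stats, covs, s2e, theta, Cinv, logL)
                if cand is not None:
                    new_covs, new_s2e = cand
                    ai_fails = 0
                else:
                    ai_fails += 1

        old_vec = _pack(covs, s2e, terms)
        new_vec = _pack(new_covs, new_s2e, terms)
        ref = new_s2e + sum(np.trace(K) / K.shape[0] for K in new_covs.values())
        scale = np.maximum(np.abs(old_vec), 1e-6 * max(ref, 1e-12))
        delta = float(np.max(np.abs(new_vec - old_vec) / scale))
        covs, s2e = new_covs, new_s2e
        if verbose:
            print(f"iter {it:3d} logL {logL:.6f} delta {delta:.3e}")
        if delta < tol:
            converged = True
            break

    logL, *_ = eng.loglik_and_chol(covs, s2e)
    history.append(logL)
    out = VarianceComponents({k: _project_psd(v) for k, v in covs.items()},
                             s2e, loglik=float(logL), converged=converged,
                             n_iter=it, history=history)
    if not converged:
        out.converged = False
    return out


def _ai_step(eng: _REMLEngine, terms, stats, covs, s2e, theta, Cinv, logL_cur):
    """One average-information Newton step; None if no acceptable step."""
    N, nf, n_eq = eng.N, eng.nf, eng.n_eq
    W = eng.W
    y = eng.d.y
    resid = y - np.asarray(W @ theta).ravel()

    # gradient
    grads = []
    fcols = []
    for t in terms:
        U, S, T = stats[t.name]
        K = covs[t.name]
        Kinv = _safe_inv(K)
        ST = S + T
        for i in range(t.k):
            for j in range(i, t.k):
                E = np.zeros((t.k, t.k))
                E[i, j] += 1.0
                E[j, i] += (1.0 if i != j else 0.0)
                M = Kinv @ E @ Kinv
                g = -0.5 * (t.n_levels * float(np.trace(E @ Kinv))
                            - float(np.sum(ST * M)))
                grads.append(g)
                Ut = U @ (E @ Kinv).T
                fcols.append(np.asarray(eng.d.term(t.name).Z @ Ut.ravel()).ravel())
    # residual parameter
    pen_trace = 0.0
    for t in terms:
        _, S_, T_ = stats[t.name]
        pen_trace += float(np.sum(_safe_inv(covs[t.name]) * T_))
    trP = (N - n_eq + pen_trace) / s2e
    ee = float(resid @ resid)
    grads.append(-0.5 * (trP - ee / s2e ** 2))
    fcols.append(resid / s2e)

    F = np.column_stack(fcols)
    B = np.asarray(W.T @ F) / s2e
    AI = 0.5 * (F.T @ F / s2e - B.T @ Cinv @ B)
    AI = 0.5 * (AI + AI.T)
    g = np.array(grads)
    try:
        step_dir = la.solve(AI + 1e-10 * np.eye(len(g)) * max(np.trace(AI), 1.0),
                            g, assume_a="pos")
    except la.LinAlgError:
        return None

    cur = _pack(covs, s2e, terms)
    step = 1.0
    for _ in range(5):
        cand = cur + step * step_dir
        cand_covs, cand_s2e = _unpack(cand, terms)
        if cand_s2e > 0:
            cand_covs = {k: _project_psd(v) for k, v in cand_covs.items()}
            logL_new, *_ = eng.loglik_and_chol(cand_covs, cand_s2e)
            if np.isfinite(logL_new) and logL_new >= logL_cur - 1e-10:
                return cand_covs, cand_s2e
        step *= 0.5
    return None


# ---------------------------------------------------------------------------
# Model selection

def compute_bic(logL: float, k: int, N: int) -> float:
    """BIC = -2 logL + k ln N (lower is better)."""
    if N <= 0:
        raise ValueError("N must be positive")
    return -2.0 * logL + k * np.log(N)


def n_free_parameters(spec: ModelSpec) -> int:
    """Free (co)variance parameters: vech of each K plus the residual."""
    ks = [o + 1 for o in spec.term_orders.values()]
    return sum(k * (k + 1) // 2 for k in ks) + 1


def select_model_order(grid, pheno: pd.DataFrame, covars: pd.DataFrame, ped,
                       K_inv: RelationshipMatrix, t_min: float, t_max: float,
                       **reml_kwargs) -> tuple[ModelSpec, pd.DataFrame]:
    """Fit the RRM over a (p, q, n) grid and pick the minimum-BIC cell.

    Ties break on fewest parameters, then lexicographic (p, q, n).  Cells
    whose REML fails are flagged non-converged and excluded from selection;
    if none converge a RuntimeError is raised.
    """
    rows = []
    for (p, q, n) in grid:
        spec = ModelSpec("rrm", p=p, q=q, n=n, t_min=t_min, t_max=t_max)
        row = dict(p=p, q=q, n=n, converged=False, loglik=np.nan,
                   n_params=n_free_parameters(spec), bic=np.nan)
        try:
            designs = build_design_matrices(spec, pheno, covars, ped)
            vc = reml_estimate(designs, K_inv, **reml_kwargs)
            row["converged"] = bool(vc.converged)
            row["loglik"] = vc.loglik
            row["bic"] = compute_bic(vc.loglik, row["n_params"], designs.n_records)
        except (np.linalg.LinAlgError, FloatingPointError, ValueError):
            pass
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    if ok.empty:
        raise RuntimeError("no grid cell converged")
    ordered = ok.sort_values(["bic", "n_params", "p", "q", "n"])
    best = ordered.iloc[0]
    best_spec = ModelSpec("rrm", p=int(best["p"]), q=int(best["q"]),
                          n=int(best["n"]), t_min=t_min, t_max=t_max)
    return best_spec, table
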