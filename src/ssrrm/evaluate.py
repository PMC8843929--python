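"""Breeding values, reliabilities, deregressed proofs and validation.

The forward-validation design mirrors a routine genetic evaluation: animals
born after a cutoff date form the validation set; their phenotypes are
masked in the training fits; prediction accuracy is the correlation of
their (training) EBV with deregressed proofs (DRP) obtained from the
full-data pedigree fit, and dispersion is |1 - b| with b the regression
slope of DRP on EBV.  Four configurations are compared: animal model vs
random-regression model, each with the pedigree (A) or single-step (H)
relationship matrix.  Heritability/variance trajectories of the
random-regression model come from the covariance-function quadratic forms
var(t) = phi(t)' K phi(t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .relmat import (Pedigree, GenotypeMatrix, RelationshipMatrix, HBlendParams,
                     build_A, build_A_inverse, build_G, subset_A, blend_G,
                     build_H_inverse)
from .mixedmodel import (ModelSpec, VarianceComponents, MMESystem,
                         build_design_matrices, assemble_and_solve_mme,
                         legendre_matrix)

__all__ = [
    "compute_ebv",
    "compute_reliability",
    "deregress",
    "forward_validate",
    "variance_trajectories",
    "validation_stats",
    "relative_gain",
    "relative_gain_report",
]


def _mean_basis(spec: ModelSpec, ages: np.ndarray) -> np.ndarray:
    if spec.kind == "animal":
        return np.ones(1)
    return legendre_matrix(ages, spec.t_min, spec.t_max, spec.p).mean(axis=0)


def _grids(spec: ModelSpec, ped: Pedigree, ages_by_animal: dict,
           default_grid: np.ndarray | None) -> dict[int, np.ndarray]:
    """Per-animal age grid; animals without records use the common grid."""
    if default_grid is None:
        if ages_by_animal:
            lo = min(a.min() for a in ages_by_animal.values())
            hi = max(a.max() for a in ages_by_animal.values())
            default_grid = np.arange(lo, hi + 1)
        else:
            default_grid = np.array([0.0])
    return {int(a): ages_by_animal.get(int(a), default_grid) for a in ped.ids}


def compute_ebv(mme: MMESystem, spec: ModelSpec, ped: Pedigree,
                default_grid: np.ndarray | None = None,
                common_grid_only: bool = False) -> pd.Series:
    """EBV per animal: the additive solution (animal model) or the average
    of phi(t)' a_k over the animal's retained test days (RRM).

    With ``common_grid_only`` every animal is averaged over the population
    grid instead of its own test days — used in forward validation so all
    EBVs (and the DRP derived from them) live on one scale.
    """
    coefs = mme.coef("additive")
    if spec.kind == "animal":
        return pd.Series(coefs[:, 0], index=ped.ids, name="ebv")
    if common_grid_only:
        if default_grid is None:
            raise ValueError("common_grid_only requires default_grid")
        ebv = coefs @ _mean_basis(spec, np.asarray(default_grid, dtype=float))
        return pd.Series(ebv, index=ped.ids, name="ebv")
    grids = _grids(spec, ped, mme.designs.ages_by_animal, default_grid)
    ebv = np.array([_mean_basis(spec, grids[int(a)]) @ coefs[i]
                    for i, a in enumerate(ped.ids)])
    return pd.Series(ebv, index=ped.ids, name="ebv")


def compute_reliability(mme: MMESystem, vc: VarianceComponents, spec: ModelSpec,
                        ped: Pedigree,
                        default_grid: np.ndarray | None = None) -> pd.Series:
    """r^2 = 1 - PEV/var_a, clipped to [0, 1].

    For the RRM both PEV and var_a refer to the *averaged* EBV: with
    m = mean phi over the animal's grid, PEV = m' PEVblock m and
    var_a = m' Ka m.
    """
    pev = mme.pev_blocks("additive")
    Ka = vc.covs["additive"]
    if spec.kind == "animal":
        var_a = np.full(ped.n, float(Ka[0, 0]))
        pev_avg = pev[:, 0, 0]
    else:
        grids = _grids(spec, ped, mme.designs.ages_by_animal, default_grid)
        m = np.array([_mean_basis(spec, grids[int(a)]) for a in ped.ids])
        var_a = np.einsum("ij,jk,ik->i", m, Ka, m)
        pev_avg = np.einsum("ij,ijk,ik->i", m, pev, m)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - pev_avg / var_a
    r2 = np.clip(np.nan_to_num(r2, nan=0.0), 0.0, 1.0)
    return pd.Series(r2, index=ped.ids, name="r2")


def deregress(ebv: pd.Series, r2: pd.Series, ped: Pedigree, heritability: float,
              c: float = 0.5, r2_floor: float = 0.10) -> pd.DataFrame:
    """Garrick-style deregressed proofs with parent-average removal.

    With lambda = (1-h^2)/h^2, alpha = 1/(0.5 - r2_PA),
    delta = (0.5 - r2_PA)/(1 - r2_i):

        Z'Z_PA = lambda (0.5 alpha - 4) + 0.5 lambda sqrt(alpha^2 + 16/delta)
        Z'Z_i  = delta Z'Z_PA + 2 lambda (2 delta - 1)
        DRP    = EBV + 2 lambda (EBV - PA) / Z'Z_i
        r2_DRP = 1 - lambda/(Z'Z_i + lambda)
        w      = (1 - h^2) / ((c + (1 - r2_DRP)/r2_DRP) h^2)

    Animals with r2 below ``r2_floor`` are flagged excluded, not dropped
    with an error.  Unknown parents contribute PA = 0 with r2_PA = 0.
    """
    if not (0 < heritability < 1):
        raise ValueError("heritability must be in (0, 1)")
    lam = (1.0 - heritability) / heritability
    sire, dam = ped.parent_indices()
    ids = ped.ids
    ebv_v = ebv.reindex(ids).to_numpy(dtype=float)
    r2_v = np.clip(r2.reindex(ids).to_numpy(dtype=float), 0.0, 1.0 - 1e-8)
    rows = []
    for i, a in enumerate(ids):
        pa = 0.0
        r2pa = 0.0
        parts = []
        for p in (sire[i], dam[i]):
            if p >= 0:
                parts.append((ebv_v[p], r2_v[p]))
        if len(parts) == 2:
            pa = 0.5 * (parts[0][0] + parts[1][0])
            r2pa = 0.25 * (parts[0][1] + parts[1][1])
        elif len(parts) == 1:
            pa = 0.5 * parts[0][0]
            r2pa = 0.25 * parts[0][1]
        r2i = r2_v[i]
        if r2i < r2_floor:
            rows.append(dict(animal=a, drp=np.nan, weight=np.nan,
                             r2_drp=np.nan, included=False,
                             reason=f"r2 {r2i:.3f} below floor {r2_floor}"))
            continue
        r2pa = min(r2pa, 0.49999)
        alpha = 1.0 / (0.5 - r2pa)
        delta = (0.5 - r2pa) / (1.0 - r2i)
        zz_pa = lam * (0.5 * alpha - 4.0) + 0.5 * lam * np.sqrt(alpha ** 2 + 16.0 / delta)
        zz_i = delta * zz_pa + 2.0 * lam * (2.0 * delta - 1.0)
        r2_drp = 1.0 - lam / (zz_i + lam) if zz_i > 0 else 0.0
        if r2_drp < r2_floor:
            # the EBV carries ~no information beyond the parent average;
            # deregressing it would just amplify noise
            rows.append(dict(animal=a, drp=np.nan, weight=np.nan,
                             r2_drp=np.nan, included=False,
                             reason=f"deregressed reliability "
                                    f"{max(r2_drp, 0.0):.3f} below floor "
                                    f"{r2_floor}"))
            continue
        drp = ebv_v[i] + 2.0 * lam * (ebv_v[i] - pa) / zz_i
        w = (1.0 - heritability) / ((c + (1.0 - r2_drp) / r2_drp) * heritability)
        rows.append(dict(animal=a, drp=float(drp), weight=float(w),
                         r2_drp=float(r2_drp), included=True, reason=""))
    return pd.DataFrame(rows)


def variance_trajectories(vc: VarianceComponents, spec: ModelSpec,
                          age_grid) -> pd.DataFrame:
    """var_a(t), var_pe(t), var_litter(t) and h^2(t) on an age grid.

    h^2(t) = var_a / (var_a + var_pe + var_litter + sigma2_e); the litter
    track enters the denominator (full phenotypic partition).
    """
    age_grid = np.atleast_1d(np.asarray(age_grid, dtype=float))
    if age_grid.size == 0:
        raise ValueError("empty age grid")
    if spec.kind != "rrm":
        raise ValueError("trajectories are defined for the RRM")
    out = {"age": age_grid}
    tracks = {}
    for name, key in (("var_a", "additive"), ("var_pe", "pe"),
                      ("var_litter", "litter")):
        K = vc.covs.get(key)
        if K is None:
            tracks[name] = np.zeros_like(age_grid)
            continue
        Phi = legendre_matrix(age_grid, spec.t_min, spec.t_max, K.shape[0] - 1)
        tracks[name] = np.einsum("ij,jk,ik->i", Phi, K, Phi)
    denom = tracks["var_a"] + tracks["var_pe"] + tracks["var_litter"] + vc.sigma2_e
    with np.errstate(divide="ignore", invalid="ignore"):
        h2 = np.where(denom > 0, tracks["var_a"] / denom, 1.0)
    out.update(tracks)
    out["h2"] = h2
    return pd.DataFrame(out)


def mean_h2(vc: VarianceComponents, spec: ModelSpec, age_grid) -> float:
    """Average daily heritability over a grid."""
    if spec.kind == "animal":
        tot = vc.sigma2_a + vc.sigma2_litter + vc.sigma2_e
        return vc.sigma2_a / tot
    return float(variance_trajectories(vc, spec, age_grid)["h2"].mean())


def deregression_h2(vc: VarianceComponents, spec: ModelSpec, age_grid,
                    n_days: float = 1.0) -> float:
    """Heritability on the scale of the trait the EBV refers to.

    The RRM EBV is the *test-period average* of the genetic curve, so its
    pseudo-record is an average of ~n_days daily records: the residual
    variance shrinks by n_days while permanent-environment and litter
    variances persist.  Garrick's lambda must be taken on this scale, not
    the daily one, or the deregression over-amplifies prediction noise.
    """
    if spec.kind == "animal":
        return mean_h2(vc, spec, age_grid)
    age_grid = np.atleast_1d(np.asarray(age_grid, dtype=float))
    comp = {}
    for key in ("additive", "pe", "litter"):
        K = vc.covs.get(key)
        if K is None:
            comp[key] = 0.0
            continue
        m = legendre_matrix(age_grid, spec.t_min, spec.t_max,
                            K.shape[0] - 1).mean(axis=0)
        comp[key] = float(m @ K @ m)
    va = comp["additive"]
    tot = va + comp["pe"] + comp["litter"] + vc.sigma2_e / max(n_days, 1.0)
    return va / tot


# ---------------------------------------------------------------------------
# Forward validation

@dataclass
class ValidationInputs:
    ped: Pedigree
    geno: GenotypeMatrix | None
    daily: pd.DataFrame
    covars: pd.DataFrame
    vc_rrm: VarianceComponents
    vc_animal: VarianceComponents
    spec_rrm: ModelSpec
    spec_animal: ModelSpec


def _relationship_set(ped: Pedigree, geno: GenotypeMatrix | None,
                      params: HBlendParams):
    A_inv = build_A_inverse(ped)
    H_inv = None
    if geno is not None and len(geno.ids) > 0:
        A = build_A(ped)
        A22 = subset_A(A, geno.ids)
        G = build_G(geno)
        Gb = blend_G(G, A22, params)
        H_inv = build_H_inverse(A_inv, A22, Gb, params, geno.ids)
    return A_inv, H_inv

def _common_grid(daily: pd.DataFrame) -> np.ndarray:
    return np.arange(daily["age"].min(), daily["age"].max() + 1, dtype=float)


def forward_validate(inputs: ValidationInputs, cutoff_date,
                     hparams: HBlendParams | None = None, *, c: float = 0.5,
                     r2_floor: float = 0.10,
                     models: tuple[str, ...] = ("animal", "rrm"),
                     matrices: tuple[str, ...] = ("A", "H")) -> pd.DataFrame:
    """Accuracy/dispersion of model x matrix configurations.

    DRP come from full-data fits with the pedigree relationship matrix;
    training fits mask the phenotypes of animals born after ``cutoff_date``
    (their EBVs propagate through relationships only).  Accuracy is the
    Pearson correlation of validation-animal EBV with DRP; the slope b of
    DRP on EBV gives dispersion |1 - b|.
    """
    hparams = hparams or HBlendParams()
    ped, daily, covars = inputs.ped, inputs.daily, inputs.covars
    cutoff = pd.Timestamp(cutoff_date)
    born = inputs.ped.table.set_index("id")["birth_date"]
    val_ids = born[born > cutoff].index.to_numpy()
    if len(val_ids) < 2:
        raise ValueError("fewer than 2 validation animals after the cutoff")

    A_inv, H_inv = _relationship_set(ped, inputs.geno, hparams)
    grid = _common_grid(daily)
    specs = {"animal": inputs.spec_animal, "rrm": inputs.spec_rrm}
    vcs = {"animal": inputs.vc_animal, "rrm": inputs.vc_rrm}

    # full-data pedigree fits -> DRP per model kind
    drp_tables: dict[str, pd.DataFrame] = {}
    for kind in models:
        designs = build_design_matrices(specs[kind], daily, covars, ped)
        mme = assemble_and_solve_mme(designs, A_inv, vcs[kind])
        ebv = compute_ebv(mme, specs[kind], ped, default_grid=grid,
                          common_grid_only=True)
        r2 = compute_reliability(mme, vcs[kind], specs[kind], ped, default_grid=grid)
        n_days = float(daily.groupby("animal")["age"].nunique().mean())
        h2 = deregression_h2(vcs[kind], specs[kind], grid, n_days)
        drp_tables[kind] = deregress(ebv, r2, ped, h2, c=c, r2_floor=r2_floor)

    train_daily = daily[~daily["animal"].isin(val_ids)]
    train_covars = covars[~covars["animal"].isin(val_ids)]

    rows = []
    for kind in models:
        drp = drp_tables[kind].set_index("animal")
        for mat in matrices:
            K_inv = A_inv if mat == "A" else H_inv
            if K_inv is None:
                raise ValueError("H matrix requested without genotypes")
            designs = build_design_matrices(specs[kind], train_daily,
                                            train_covars, ped)
            mme = assemble_and_solve_mme(designs, K_inv, vcs[kind])
            ebv = compute_ebv(mme, specs[kind], ped, default_grid=grid,
                              common_grid_only=True)
            sub = drp.loc[[a for a in val_ids if a in drp.index]]
            sub = sub[sub["included"]]
            x = ebv.loc[sub.index].to_numpy()
            y = sub["drp"].to_numpy()
            if len(x) < 2:
                raise ValueError("fewer than 2 validation animals with DRP")
            acc, b, disp = validation_stats(x, y)
            rows.append(dict(model=kind, matrix=mat, accuracy=acc, slope=b,
                             dispersion=disp, n_validation=len(x)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Worked arithmetic on reported accuracy pairs

def validation_stats(ebv: np.ndarray, drp: np.ndarray) -> tuple[float, float, float]:
    """(accuracy, slope, dispersion): Pearson correlation of DRP with EBV,
    regression slope of DRP on EBV, and |1 - slope|."""
    ebv = np.asarray(ebv, dtype=float)
    drp = np.asarray(drp, dtype=float)
    if len(ebv) < 2 or len(ebv) != len(drp):
        raise ValueError("need >= 2 paired EBV/DRP values")
    acc = float(np.corrcoef(ebv, drp)[0, 1])
    b = float(np.polyfit(ebv, drp, 1)[0])
    return acc, b, abs(1.0 - b)


def relative_gain(acc_new: float, acc_base: float) -> float:
    """Percent accuracy gain of one configuration over another."""
    if acc_base == 0:
        raise ZeroDivisionError("baseline accuracy is zero")
    return (acc_new / acc_base - 1.0) * 100.0


def relative_gain_report(report: pd.DataFrame, ndigits: int = 1) -> pd.DataFrame:
    """RRM-over-animal-model accuracy gains per relationship matrix.

    ``report`` has columns model/matrix/accuracy (as from
    :func:`forward_validate`).  Returns one row per matrix with the gain in
    percent, rounded to ``ndigits``.
    """
    rows = []
    for mat, g in report.groupby("matrix"):
        acc = g.set_index("model")["accuracy"]
        gain = relative_gain(acc["rrm"], acc["animal"])
        rows.append(dict(matrix=mat, accuracy_animal=acc["animal"],
                         accuracy_rrm=acc["rrm"],
                         gain_pct=round(gain, ndigits)))
    return pd.DataFrame(rows)
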