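"""Synthetic pedigrees, genotypes and longitudinal feed-intake phenotypes.

The generator emulates a performance-tested boar population: a pedigree of
non-overlapping generations with random mating, gene-dropped SNP genotypes,
and daily feed-intake records over an age window of roughly 99-172 days.
Each animal-day record is

    DFI = YS + pen + b1*ADG + b2*BFA + b3*SBW + b4*MBW
          + phi(t)' litter + phi(t)' a + phi(t)' pe + e

with normalised Legendre basis phi of standardised age, additive coefficient
vectors with covariance Ka (x) A, permanent-environment coefficients
pe ~ N(0, Kpe) per animal, litter coefficients shared by full sibs, and
i.i.d. residual e ~ N(0, sigma2_e).  By default the additive curves are
marker-determined (each SNP carries a small coefficient-vector effect on
the same gene-dropped genotypes the genotype matrix reports), so realized
genomic relationships are informative about the simulated genetics; the
parent-average + Mendelian-sampling recursion emerges through allele
transmission.  A pedigree-recursion mode (genomic_additive=False) draws
the coefficients independently of the markers.

An optional visit-level layer splits each daily intake into 3-12 feeder
visits and attaches Poisson error counts (with a configurable per-error
intake perturbation) so the preprocessing stage has something to undo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .relmat import Pedigree, GenotypeMatrix, inbreeding
from .mixedmodel import legendre_matrix

__all__ = [
    "SimConfig",
    "TrueEffects",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_effects_and_phenotypes",
    "simulate_visits",
]


def _default_Ka() -> np.ndarray:
    return np.diag([0.023, 0.03, 0.035])


def _default_Kpe() -> np.ndarray:
    return np.diag([0.04, 0.002])


def _default_Klitter() -> np.ndarray:
    return np.diag([0.02, 0.002])


@dataclass
class SimConfig:
    """Study conditions for the synthetic population.

    Covariance defaults reconcile the trait's known anchors jointly: a
    U-shaped daily heritability (~0.13 mid-test rising to ~0.46 at the
    window edges), an overall test-average heritability near 0.3, and a
    flat, visible permanent-environment track, on a daily intake of
    ~2.4 kg/d.  Covariate means/SDs follow the descriptive
    statistics of a finishing-boar test (start weight 49.2 +/- 10.4 kg,
    ADG 0.91 +/- 0.13 kg/d, back fat 12.2 +/- 2.4 mm).
    """

    n_founders: int = 60
    n_generations: int = 2
    n_matings: int = 30
    offspring_per_mating: int = 5
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    prop_genotyped: float = 0.7
    age_range: tuple[int, int] = (99, 172)
    Ka_true: np.ndarray = field(default_factory=_default_Ka)
    Kpe_true: np.ndarray = field(default_factory=_default_Kpe)
    Klitter_true: np.ndarray = field(default_factory=_default_Klitter)
    sigma2_e: float = 0.135
    n_ys_levels: int = 4
    n_pen_levels: int = 5
    sigma_ys: float = 0.15
    sigma_pen: float = 0.10
    betas: tuple[float, float, float, float] = (1.0, 0.005, 0.002, 0.05)
    mean_intake: float = 0.0  # baseline absorbed by the intercept / YS levels
    sbw_mean: float = 49.24
    sbw_sd: float = 10.43
    adg_mean: float = 0.91
    adg_sd: float = 0.13
    bfa_mean: float = 12.15
    bfa_sd: float = 2.42
    window_range: tuple[int, int] = (48, 74)  # recorded days incl. adaptation week
    genomic_additive: bool = True  # breeding values carried by the SNPs
    phenotype_founders: bool = False
    error_rate: float = 0.2  # Poisson mean of daily error counts
    error_effect: float = -0.05  # kg intake perturbation per error
    visit_range: tuple[int, int] = (3, 12)
    founder_birth: date = date(2017, 3, 1)
    generation_gap_days: int = 300
    birth_jitter_days: int = 60
    cutoff_date: date | None = None  # default: just before the last generation
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        t0, t1 = self.age_range
        if t0 >= t1:
            raise ValueError("age_range must have t_min < t_max")
        for name in ("Ka_true", "Kpe_true", "Klitter_true"):
            K = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, K)
            if K.ndim != 2 or K.shape[0] != K.shape[1]:
                raise ValueError(f"{name} must be square")
            if np.abs(K - K.T).max() > 1e-10:
                raise ValueError(f"{name} must be symmetric")
            if K.size and np.linalg.eigvalsh(K).min() < -1e-10:
                raise ValueError(f"{name} must be positive semidefinite")
        if self.sigma2_e < 0:
            raise ValueError("sigma2_e must be >= 0")
        w0, w1 = self.window_range
        if w0 < 41:
            raise ValueError("window_range lower bound must be >= 41 days "
                             "(>= 34 must survive the first-week cut)")
        if w1 > t1 - t0 + 1:
            raise ValueError("window_range upper bound exceeds the age range")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))

    @property
    def orders(self) -> tuple[int, int, int]:
        """(p, q, n) Legendre orders implied by the true covariance matrices."""
        return (self.Ka_true.shape[0] - 1,
                self.Kpe_true.shape[0] - 1,
                self.Klitter_true.shape[0] - 1)


@dataclass
class TrueEffects:
    """Realised simulation truth, keyed by pedigree order / level ids."""

    additive: np.ndarray          # (n_animals, p+1)
    permanent_env: np.ndarray     # (n_animals, q+1); zero rows for unphenotyped
    litter: dict[int, np.ndarray]  # litter id -> (n+1,) coefficients
    ys_values: np.ndarray
    pen_values: np.ndarray
    betas: tuple[float, float, float, float]

    def true_ebv(self, cfg: SimConfig, ages: np.ndarray) -> np.ndarray:
        """Average true genetic merit phi(t)'a over an age grid, per animal."""
        Phi = legendre_matrix(ages, cfg.age_range[0], cfg.age_range[1],
                              cfg.Ka_true.shape[0] - 1)
        m = Phi.mean(axis=0)
        return self.additive @ m


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Non-overlapping generations; sires/dams sampled from the previous one.

    Founders have unknown parents and singleton litters; each mating
    produces one litter of full sibs.  Sexes alternate deterministically so
    every generation contains both sires and dams.
    """
    if cfg.n_founders < 2 and cfg.n_generations > 0:
        raise ValueError("need at least one sire and one dam to breed from")
    rng = cfg.rng(1)
    rows = []
    next_id = 1
    next_litter = 1
    prev_gen: list[dict] = []
    for g in range(cfg.n_generations + 1):
        base = cfg.founder_birth + timedelta(days=g * cfg.generation_gap_days)
        gen_rows = []
        if g == 0:
            for i in range(cfg.n_founders):
                gen_rows.append(dict(
                    id=next_id, sire=0, dam=0,
                    birth_date=base + timedelta(days=int(rng.integers(0, cfg.birth_jitter_days + 1))),
                    litter=next_litter, sex="M" if i % 2 == 0 else "F",
                    generation=0,
                ))
                next_id += 1
                next_litter += 1
        else:
            sires = [r for r in prev_gen if r["sex"] == "M"]
            dams = [r for r in prev_gen if r["sex"] == "F"]
            if not sires or not dams:
                raise ValueError(f"generation {g - 1} lacks a sire or a dam")
            k = 0
            for _ in range(cfg.n_matings):
                s = sires[rng.integers(0, len(sires))]
                d = dams[rng.integers(0, len(dams))]
                lit = next_litter
                next_litter += 1
                for _ in range(cfg.offspring_per_mating):
                    gen_rows.append(dict(
                        id=next_id, sire=s["id"], dam=d["id"],
                        birth_date=base + timedelta(days=int(rng.integers(0, cfg.birth_jitter_days + 1))),
                        litter=lit, sex="M" if k % 2 == 0 else "F",
                        generation=g,
                    ))
                    next_id += 1
                    k += 1
        rows.extend(gen_rows)
        prev_gen = gen_rows
    df = pd.DataFrame(rows)
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    df["genotyped"] = rng.random(len(df)) < cfg.prop_genotyped
    return Pedigree(df)


def default_cutoff(cfg: SimConfig, ped: Pedigree) -> pd.Timestamp:
    """Birth-date threshold putting the last generation in the validation set."""
    if cfg.cutoff_date is not None:
        return pd.Timestamp(cfg.cutoff_date)
    last = ped.table["generation"].max()
    first_last = ped.table.loc[ped.table["generation"] == last, "birth_date"].min()
    return first_last - pd.Timedelta(days=1)


def _gene_drop(ped: Pedigree, cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Genotype counts for *all* pedigree animals plus founder frequencies.

    Deterministic given cfg.seed, so the emitted genotype matrix and the
    marker-determined breeding values see the same realisation.
    """
    rng = cfg.rng(2)
    n, m = ped.n, cfg.n_snps
    freqs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    sire, dam = ped.parent_indices()
    # two haplotypes per animal, boolean (carries alternative allele)
    hap = np.zeros((n, 2, m), dtype=bool)
    cols = np.arange(m)
    for i in range(n):
        for h, p in ((0, sire[i]), (1, dam[i])):
            if p < 0:
                hap[i, h] = rng.random(m) < freqs
            else:
                pick = rng.integers(0, 2, size=m)
                hap[i, h] = hap[p, pick, cols]
    return hap.sum(axis=1).astype(np.int8), freqs


def simulate_genotypes(ped: Pedigree, cfg: SimConfig) -> GenotypeMatrix:
    """Gene dropping over independent loci; founders at Hardy-Weinberg.

    Only animals flagged genotyped are emitted.
    """
    counts, _ = _gene_drop(ped, cfg)
    mask = ped.table["genotyped"].astype(bool).to_numpy()
    snp_ids = np.array([f"snp{j + 1}" for j in range(cfg.n_snps)])
    return GenotypeMatrix(ped.ids[mask], snp_ids, counts[mask])


def _draw_coefficients(rng: np.random.Generator, ped: Pedigree, K: np.ndarray) -> np.ndarray:
    """Additive coefficient vectors with covariance K (x) A via the pedigree
    recursion: founders ~ N(0, K); offspring = parent average + Mendelian
    sampling with variance d_i * K, d_i from the inbreeding of the parents."""
    k = K.shape[0]
    n = ped.n
    if k == 0 or not K.any():
        return np.zeros((n, k))
    L = np.linalg.cholesky(K + 1e-12 * np.trace(K) / max(k, 1) * np.eye(k))
    sire, dam = ped.parent_indices()
    _, d = inbreeding(ped)
    a = np.zeros((n, k))
    z = rng.standard_normal((n, k))
    for i in range(n):
        pa = np.zeros(k)
        if sire[i] >= 0:
            pa += 0.5 * a[sire[i]]
        if dam[i] >= 0:
            pa += 0.5 * a[dam[i]]
        a[i] = pa + np.sqrt(d[i]) * (L @ z[i])
    return a


def simulate_effects_and_phenotypes(
    ped: Pedigree, cfg: SimConfig
) -> tuple[TrueEffects, pd.DataFrame, pd.DataFrame]:
    """Realise the generative model and emit daily records plus covariates.

    Returns (effects, daily table, covariate table).  The daily table has
    one row per animal-day: animal, age, ys, pen, intake (kg), body_weight
    (kg), error_count (0 here; the visit layer adds errors), test_start_age.
    """
    rng = cfg.rng(3)
    p, q, nlit = cfg.orders
    t0, t1 = cfg.age_range

    if cfg.genomic_additive and cfg.n_snps > 0 and cfg.Ka_true.any():
        # marker-determined breeding-value curves: each SNP carries a small
        # (p+1)-vector effect; scaling gives founder coefficients ~ N(0, Ka)
        counts, freqs = _gene_drop(ped, cfg)
        denom = 2.0 * float(np.sum(freqs * (1.0 - freqs)))
        k = p + 1
        L = np.linalg.cholesky(cfg.Ka_true + 1e-12 * np.eye(k)
                               * max(np.trace(cfg.Ka_true), 1e-12))
        U = rng.standard_normal((cfg.n_snps, k)) @ L.T / np.sqrt(denom)
        a = (counts - 2.0 * freqs) @ U
    else:
        a = _draw_coefficients(rng, ped, cfg.Ka_true)

    tab = ped.table
    n = ped.n
    pheno_mask = np.ones(n, dtype=bool)
    if not cfg.phenotype_founders:
        pheno_mask = (tab["generation"].to_numpy() > 0) if "generation" in tab else pheno_mask
    if not pheno_mask.any():
        pheno_mask = np.ones(n, dtype=bool)

    pe = np.zeros((n, q + 1))
    if cfg.Kpe_true.any():
        Lpe = np.linalg.cholesky(cfg.Kpe_true + 1e-12 * np.eye(q + 1) * max(np.trace(cfg.Kpe_true), 1e-12))
        pe[pheno_mask] = rng.standard_normal((pheno_mask.sum(), q + 1)) @ Lpe.T

    litters = tab["litter"].to_numpy()
    litter_ids = np.unique(litters[pheno_mask])
    litter_eff: dict[int, np.ndarray] = {}
    if cfg.Klitter_true.any():
        Ll = np.linalg.cholesky(cfg.Klitter_true + 1e-12 * np.eye(nlit + 1) * max(np.trace(cfg.Klitter_true), 1e-12))
        for lid in litter_ids:
            litter_eff[int(lid)] = Ll @ rng.standard_normal(nlit + 1)
    else:
        for lid in litter_ids:
            litter_eff[int(lid)] = np.zeros(nlit + 1)

    ys_values = rng.normal(0.0, cfg.sigma_ys, size=cfg.n_ys_levels)
    pen_values = rng.normal(0.0, cfg.sigma_pen, size=cfg.n_pen_levels)

    # year-season from birth-date order, pen at random
    order = np.argsort(tab["birth_date"].to_numpy(), kind="stable")
    ys_level = np.empty(n, dtype=int)
    ys_level[order] = (np.arange(n) * cfg.n_ys_levels) // n
    pen_level = rng.integers(0, cfg.n_pen_levels, size=n)

    b1, b2, b3, b4 = cfg.betas
    daily_rows = []
    cov_rows = []
    effects = TrueEffects(a, pe, litter_eff, ys_values, pen_values, cfg.betas)

    for i in np.flatnonzero(pheno_mask):
        w = int(rng.integers(cfg.window_range[0], cfg.window_range[1] + 1))
        start = int(rng.integers(t0, t1 - w + 2))
        ages = np.arange(start, start + w)
        sbw = rng.normal(cfg.sbw_mean, cfg.sbw_sd)
        sbw = max(sbw, 20.0)
        adg = max(rng.normal(cfg.adg_mean, cfg.adg_sd), 0.3)
        bfa = max(rng.normal(cfg.bfa_mean, cfg.bfa_sd), 4.0)
        bw = sbw + adg * (ages - start)
        mbw = float(np.mean(bw) ** 0.75)
        fixed = (cfg.mean_intake + ys_values[ys_level[i]] + pen_values[pen_level[i]]
                 + b1 * adg + b2 * bfa + b3 * sbw + b4 * mbw)
        Phi_a = legendre_matrix(ages, t0, t1, p)
        Phi_pe = legendre_matrix(ages, t0, t1, q)
        Phi_l = legendre_matrix(ages, t0, t1, nlit)
        lit = litter_eff[int(litters[i])]
        signal = fixed + Phi_a @ a[i] + Phi_pe @ pe[i] + Phi_l @ lit
        e = rng.normal(0.0, np.sqrt(cfg.sigma2_e), size=w) if cfg.sigma2_e > 0 else 0.0
        intake = signal + e
        aid = int(ped.ids[i])
        for j, t in enumerate(ages):
            daily_rows.append((aid, int(t), ys_level[i] + 1, pen_level[i] + 1,
                               float(intake[j] if np.ndim(intake) else intake),
                               float(bw[j]), 0, start))
        cov_rows.append(dict(animal=aid, sbw=float(sbw), fbw=float(bw[-1]),
                             bfa=float(bfa), adg=float(adg), mbw=mbw,
                             on_age=start, off_age=int(ages[-1]),
                             adfi=float(np.mean(intake))))

    daily = pd.DataFrame(daily_rows, columns=[
        "animal", "age", "ys", "pen", "intake", "body_weight",
        "error_count", "test_start_age"])
    covars = pd.DataFrame(cov_rows)
    return effects, daily, covars


def simulate_visits(daily: pd.DataFrame, cfg: SimConfig) -> pd.DataFrame:
    """Split daily records into feeder visits with error counts attached.

    Per day: 3-12 visits whose intakes sum exactly to the observed daily
    intake (= clean intake + error_effect * error_count, floored at 0);
    visit body weights jitter around the daily weight; error counts are
    Poisson(error_rate) capped at the visit count, with the first visits
    flagged.
    """
    if (daily["intake"] < -1e-12).any():
        raise ValueError("daily intake must be non-negative")
    rng = cfg.rng(4)
    lo, hi = cfg.visit_range
    n = len(daily)
    nv = rng.integers(lo, hi + 1, size=n)
    errs = np.minimum(rng.poisson(cfg.error_rate, size=n), nv)
    observed = np.maximum(daily["intake"].to_numpy()
                          + cfg.error_effect * errs, 0.0)
    tot = int(nv.sum())
    rec = np.repeat(np.arange(n), nv)
    starts = np.concatenate(([0], np.cumsum(nv)[:-1]))
    visit_no = np.arange(tot) - np.repeat(starts, nv)
    # Dirichlet split via normalised gammas; last visit absorbs fp drift so
    # per-day sums reproduce the observed intake exactly
    g = rng.gamma(1.0, size=tot)
    shares = g / np.add.reduceat(g, starts)[rec]
    intakes = shares * observed[rec]
    last = np.cumsum(nv) - 1
    intakes[last] = observed - (np.add.reduceat(intakes, starts) - intakes[last])
    # scale readings quantised to 0.5 kg so the daily mode is meaningful
    weights = np.round((daily["body_weight"].to_numpy()[rec]
                        + rng.normal(0.0, 0.5, size=tot)) * 2.0) / 2.0
    out = pd.DataFrame({
        "animal": daily["animal"].to_numpy()[rec],
        "age": daily["age"].to_numpy()[rec],
        "visit": visit_no + 1,
        "intake": intakes,
        "body_weight": weights,
        "error": (visit_no < errs[rec]).astype(int),
    })
    for col in ("test_start_age", "ys", "pen"):
        if col in daily.columns:
            out[col] = daily[col].to_numpy()[rec]
    return out
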