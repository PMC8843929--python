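"""End-to-end orchestration: simulate/load -> preprocess -> relationship
matrices -> (order selection) -> REML -> trajectories -> forward validation.

Every stage writes text artifacts into the run directory and logs record
counts; a manifest records the seed, the configuration fingerprint and the
per-stage row accounting, so a rerun with the same config and seed is
bit-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .config import PipelineConfig, config_fingerprint
from .preprocess import (aggregate_visits, filter_test_window,
                         adjust_for_error_counts, derive_covariates)
from .relmat import (HBlendParams, build_A, build_A_inverse, build_G,
                     subset_A, blend_G, build_H_inverse)
from .mixedmodel import (ModelSpec, build_design_matrices, reml_estimate,
                         compute_bic, n_free_parameters, select_model_order)
from .evaluate import (ValidationInputs, forward_validate,
                       variance_trajectories, relative_gain_report)
from .simdata import (simulate_pedigree, simulate_genotypes,
                      simulate_effects_and_phenotypes, simulate_visits,
                      default_cutoff)

log = logging.getLogger("ssrrm")

__all__ = ["run_pipeline"]


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage '{stage}' failed: {err}")
        self.stage = stage


def _stage(name, counts, func, *args, **kwargs):
    try:
        out = func(*args, **kwargs)
    except Exception as e:  # noqa: BLE001 - re-raised with stage context
        raise StageError(name, e) from e
    return out


def run_pipeline(cfg: PipelineConfig) -> Path:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # ---- acquire data ----------------------------------------------------
    if cfg.sim is not None:
        sim = cfg.sim
        ped = _stage("simulate_pedigree", counts, simulate_pedigree, sim)
        geno = _stage("simulate_genotypes", counts, simulate_genotypes, ped, sim)
        effects, clean_daily, true_covars = _stage(
            "simulate_phenotypes", counts, simulate_effects_and_phenotypes, ped, sim)
        visits = _stage("simulate_visits", counts, simulate_visits, clean_daily, sim)
        daily_raw = _stage("aggregate_visits", counts, aggregate_visits, visits)
        bfa = true_covars.set_index("animal")["bfa"]
        cutoff = default_cutoff(sim, ped)
    else:
        ped = _stage("read_pedigree", counts, sio.read_pedigree, cfg.pedigree_path)
        geno = (sio.read_genotypes(cfg.genotypes_path)
                if cfg.genotypes_path else None)
        daily_raw = _stage("read_phenotypes", counts, sio.read_table,
                           cfg.phenotypes_path)
        cov_in = sio.read_table(cfg.covariates_path)
        bfa = cov_in.set_index("animal")["bfa"]
        if cfg.cutoff_date is None:
            raise StageError("config", ValueError("cutoff_date required with file inputs"))
        cutoff = pd.Timestamp(cfg.cutoff_date)
    counts["animals_pedigree"] = ped.n
    counts["animals_genotyped"] = 0 if geno is None else len(geno.ids)
    counts["daily_records_raw"] = len(daily_raw)
    log.info("pedigree %d animals, %d genotyped; %d raw daily records",
             ped.n, counts["animals_genotyped"], len(daily_raw))

    # ---- preprocess ------------------------------------------------------
    daily = _stage("filter_test_window", counts, filter_test_window,
                   daily_raw, cfg.min_days, cfg.adaptation_days)
    counts["daily_records_filtered"] = len(daily)
    counts["animals_phenotyped"] = daily["animal"].nunique()
    covars0 = _stage("derive_covariates", counts, derive_covariates, daily, bfa)
    daily = _stage("adjust_for_error_counts", counts, adjust_for_error_counts,
                   daily, covars0)
    covars = _stage("derive_covariates_final", counts, derive_covariates,
                    daily, bfa)
    log.info("%d records on %d animals after filters",
             len(daily), counts["animals_phenotyped"])

    sio.write_pedigree(ped, outdir / "pedigree.tsv")
    if geno is not None and len(geno.ids):
        sio.write_genotypes(geno, outdir / "genotypes.tsv")
    sio.write_table(daily, outdir / "daily.tsv")
    sio.write_table(covars, outdir / "covariates.tsv")

    # ---- relationship matrices ------------------------------------------
    A_inv = _stage("build_A_inverse", counts, build_A_inverse, ped)
    sio.write_sparse_matrix(A_inv, outdir / "A_inverse.txt")
    if geno is not None and len(geno.ids):
        A = build_A(ped)
        A22 = subset_A(A, geno.ids)
        G = _stage("build_G", counts, build_G, geno)
        Gb = blend_G(G, A22, cfg.hblend)
        H_inv = _stage("build_H_inverse", counts, build_H_inverse,
                       A_inv, A22, Gb, cfg.hblend, geno.ids)
        sio.write_sparse_matrix(H_inv, outdir / "H_inverse.txt")

    t_min = float(daily["age"].min())
    t_max = float(daily["age"].max())

    # ---- model order / REML ----------------------------------------------
    reml_kw = dict(tol=cfg.reml_tol, max_iter=cfg.reml_max_iter)
    if cfg.select_order and len(cfg.grid) > 1:
        spec_rrm, bic_table = _stage(
            "select_model_order", counts, select_model_order,
            cfg.grid, daily, covars, ped, A_inv, t_min, t_max, **reml_kw)
        sio.write_table(bic_table, outdir / "bic_table.tsv")
        designs = build_design_matrices(spec_rrm, daily, covars, ped)
        vc_rrm = reml_estimate(designs, A_inv, **reml_kw)
    else:
        p, q, n = cfg.orders
        spec_rrm = ModelSpec("rrm", p=p, q=q, n=n, t_min=t_min, t_max=t_max)
        designs = build_design_matrices(spec_rrm, daily, covars, ped)
        vc_rrm = _stage("reml_rrm", counts, reml_estimate, designs, A_inv,
                        **reml_kw)
        bic_table = pd.DataFrame([dict(
            p=p, q=q, n=n, converged=vc_rrm.converged, loglik=vc_rrm.loglik,
            n_params=n_free_parameters(spec_rrm),
            bic=compute_bic(vc_rrm.loglik, n_free_parameters(spec_rrm),
                            designs.n_records))])
        sio.write_table(bic_table, outdir / "bic_table.tsv")
    sio.write_varcomp(vc_rrm, outdir / "varcomp_rrm.json",
                      meta=dict(kind="rrm", p=spec_rrm.p, q=spec_rrm.q,
                                n=spec_rrm.n, t_min=t_min, t_max=t_max,
                                seed=cfg.seed))

    spec_animal = ModelSpec("animal", t_min=t_min, t_max=t_max)
    designs_am = build_design_matrices(spec_animal, daily, covars, ped)
    vc_animal = _stage("reml_animal", counts, reml_estimate, designs_am, A_inv,
                       **reml_kw)
    sio.write_varcomp(vc_animal, outdir / "varcomp_animal.json",
                      meta=dict(kind="animal", seed=cfg.seed))

    # ---- trajectories ----------------------------------------------------
    grid_ages = np.arange(t_min, t_max + 1)
    traj = _stage("variance_trajectories", counts, variance_trajectories,
                  vc_rrm, spec_rrm, grid_ages)
    sio.write_table(traj, outdir / "trajectories.tsv")

    # ---- forward validation ----------------------------------------------
    matrices = ("A", "H") if (geno is not None and len(geno.ids)) else ("A",)
    inputs = ValidationInputs(ped, geno, daily, covars, vc_rrm, vc_animal,
                              spec_rrm, spec_animal)
    report = _stage("forward_validate", counts, forward_validate, inputs,
                    cutoff, cfg.hblend, c=cfg.garrick_c,
                    r2_floor=cfg.r2_floor, matrices=matrices)
    sio.write_table(report, outdir / "validation_report.tsv")
    gains = relative_gain_report(report)
    sio.write_table(gains, outdir / "relative_gains.tsv")

    manifest = dict(seed=cfg.seed, config_hash=config_fingerprint(cfg),
                    counts=counts, cutoff_date=str(pd.Timestamp(cutoff).date()),
                    orders=dict(p=spec_rrm.p, q=spec_rrm.q, n=spec_rrm.n))
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outdir
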