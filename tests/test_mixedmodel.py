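"""Legendre basis, design assembly, MME solutions, REML, BIC."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ssrrm import (ModelSpec, SimConfig, VarianceComponents,
                   assemble_and_solve_mme, build_A, build_A_inverse,
                   build_design_matrices, compute_bic, legendre_basis,
                   n_free_parameters, reml_estimate, select_model_order,
                   simulate_effects_and_phenotypes, simulate_pedigree)
from ssrrm.mixedmodel import (DesignBundle, MMESystem, RandomTerm,
                              legendre_matrix)
from ssrrm.preprocess import filter_test_window

from conftest import dense_blup_oracle, make_pedigree


class TestLegendreBasis:
    def test_constant_term_closed_form(self):
        assert legendre_basis(120, 99, 172, 0)[0] == pytest.approx(
            np.sqrt(0.5), abs=1e-10)

    def test_endpoint_mapping(self):
        lo = legendre_basis(99, 99, 172, 2)
        hi = legendre_basis(172, 99, 172, 2)
        # P_m(-1) = (-1)^m, P_m(1) = 1 times the normalisation
        norm = np.sqrt((2 * np.arange(3) + 1) / 2)
        np.testing.assert_allclose(lo, norm * np.array([1, -1, 1]), atol=1e-12)
        np.testing.assert_allclose(hi, norm, atol=1e-12)

    def test_value_at_lower_bound_order2(self):
        np.testing.assert_allclose(legendre_basis(99, 99, 172, 2),
                                   [0.7071067812, -1.2247448714, 1.5811388301],
                                   atol=1e-9)

    def test_orthonormal_by_gauss_quadrature(self):
        nodes, weights = np.polynomial.legendre.leggauss(40)
        ages = (nodes + 1) / 2 * (172 - 99) + 99
        Phi = legendre_matrix(ages, 99, 172, 5)
        gram = (Phi * weights[:, None]).T @ Phi
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-10)

    def test_age_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            legendre_basis(98, 99, 172, 2)


@pytest.fixture(scope="module")
def sim_designs(small_sim):
    cfg, ped, effects, daily, covars = small_sim
    spec = ModelSpec("rrm", p=2, q=1, n=1, t_min=99, t_max=172)
    return cfg, ped, daily, covars, spec, build_design_matrices(
        spec, daily, covars, ped)


class TestDesignMatrices:
    def test_fixed_column_bookkeeping(self, sim_designs):
        cfg, ped, daily, covars, spec, designs = sim_designs
        n_ys = daily["ys"].nunique()
        n_pen = daily["pen"].nunique()
        assert designs.X.shape[1] == (n_ys - 1) + (n_pen - 1) + 1 + 4
        add = designs.term("additive")
        assert add.Z.shape[1] == 3 * ped.n

    def test_rrm_row_carries_basis_at_that_age(self, sim_designs):
        cfg, ped, daily, covars, spec, designs = sim_designs
        add = designs.term("additive")
        row = daily.reset_index(drop=True).sort_values(
            ["animal", "age"]).reset_index(drop=True)
        i = int(row.index[row["age"] == row["age"].min()][0])
        dense_row = add.Z[i].toarray().ravel()
        vals = dense_row[dense_row != 0]
        np.testing.assert_allclose(
            vals, legendre_basis(row.loc[i, "age"], 99, 172, 2), atol=1e-12)

    def test_animal_model_additive_incidence_is_identity(self):
        ped = make_pedigree([(i, 0, 0) for i in range(1, 6)])
        daily = pd.DataFrame(dict(animal=np.repeat(np.arange(1, 6), 2),
                                  age=np.tile([100, 101], 5), ys=1, pen=1,
                                  intake=2.0, body_weight=50.0, error_count=0))
        covars = pd.DataFrame(dict(animal=np.arange(1, 6), adg=0.9, bfa=12.0,
                                   sbw=50.0, mbw=25.0, adfi=2.0))
        spec = ModelSpec("animal", covariates=())
        designs = build_design_matrices(spec, daily, covars, ped)
        np.testing.assert_allclose(designs.term("additive").Z.toarray(),
                                   np.eye(5))

    def test_unknown_animal_rejected(self, sim_designs):
        cfg, ped, daily, covars, spec, _ = sim_designs
        bad = daily.copy()
        bad.loc[bad.index[0], "animal"] = 99999
        with pytest.raises(ValueError, match="missing from the pedigree"):
            build_design_matrices(spec, bad, covars, ped)


def single_term_bundle(y, groups, n_levels):
    """Minimal one-way design: intercept + one random intercept term."""
    Z = sp.csr_matrix((np.ones(len(y)), (np.arange(len(y)), groups)),
                      shape=(len(y), n_levels))
    return DesignBundle(
        spec=ModelSpec("animal"), y=np.asarray(y, dtype=float),
        X=np.ones((len(y), 1)), fixed_names=["intercept"],
        terms=[RandomTerm("group", np.arange(n_levels), 1, Z)],
        record_animals=np.asarray(groups), ages_by_animal={})


class TestMMESolutions:
    def test_intercept_only_solution_is_the_mean(self):
        y = np.array([1.0, 2.0, 6.0])
        bundle = DesignBundle(ModelSpec("animal"), y, np.ones((3, 1)),
                              ["intercept"], [], np.arange(3), {})
        vc = VarianceComponents({}, sigma2_e=1.0)
        mme = MMESystem(bundle, None, vc)
        assert mme.solve()[0] == pytest.approx(y.mean())

    @pytest.mark.parametrize("kind", ["rrm", "animal"])
    def test_matches_dense_gls_blup_oracle(self, small_sim, kind):
        cfg, ped, effects, daily, covars = small_sim
        sub_animals = daily["animal"].unique()[:12]
        pheno = daily[daily["animal"].isin(sub_animals)]
        cov = covars[covars["animal"].isin(sub_animals)]
        spec = ModelSpec(kind, p=1, q=1, n=1, t_min=99, t_max=172)
        designs = build_design_matrices(spec, pheno, cov, ped)
        if kind == "rrm":
            vc = VarianceComponents({"litter": np.diag([.02, .002]),
                                     "additive": np.diag([.05, .01]),
                                     "pe": np.diag([.04, .005])}, 0.08)
        else:
            vc = VarianceComponents({"litter": [[0.01]],
                                     "additive": [[0.05]]}, 0.03)
        mme = assemble_and_solve_mme(designs, build_A_inverse(ped), vc)
        oracle = dense_blup_oracle(designs, build_A(ped).dense(), vc)
        np.testing.assert_allclose(mme.solution, oracle, atol=1e-6)

    def test_additive_solutions_shrink_in_ridge_limit(self, small_sim):
        cfg, ped, effects, daily, covars = small_sim
        spec = ModelSpec("rrm", p=1, q=1, n=1, t_min=99, t_max=172)
        designs = build_design_matrices(spec, daily, covars, ped)
        A_inv = build_A_inverse(ped)
        norms = []
        for s in (0.05, 0.005, 0.00005):
            vc = VarianceComponents({"litter": np.diag([.02, .002]),
                                     "additive": s * np.eye(2),
                                     "pe": np.diag([.04, .005])}, 0.08)
            mme = assemble_and_solve_mme(designs, A_inv, vc)
            norms.append(np.linalg.norm(mme.coef("additive")))
        assert norms[0] > norms[1] > norms[2]

    def test_solution_invariant_to_record_order(self, small_sim):
        cfg, ped, effects, daily, covars = small_sim
        spec = ModelSpec("rrm", p=1, q=1, n=1, t_min=99, t_max=172)
        vc = VarianceComponents({"litter": np.diag([.02, .002]),
                                 "additive": np.diag([.05, .01]),
                                 "pe": np.diag([.04, .005])}, 0.08)
        A_inv = build_A_inverse(ped)
        d1 = build_design_matrices(spec, daily, covars, ped)
        shuffled = daily.sample(frac=1.0, random_state=0)
        d2 = build_design_matrices(spec, shuffled, covars, ped)
        m1 = assemble_and_solve_mme(d1, A_inv, vc)
        m2 = assemble_and_solve_mme(d2, A_inv, vc)
        np.testing.assert_allclose(m1.solution, m2.solution, atol=1e-8)

    def test_confounded_fixed_levels_reported(self, small_sim):
        cfg, ped, effects, daily, covars = small_sim
        bad = daily.copy()
        bad["pen"] = bad["ys"]  # pen now a copy of year-season
        spec = ModelSpec("rrm", p=1, q=1, n=1, t_min=99, t_max=172)
        with pytest.raises(ValueError, match="rank deficient"):
            build_design_matrices(spec, bad, covars, ped)


class TestREML:
    def test_balanced_one_way_matches_anova_closed_form(self):
        rng = np.random.default_rng(3)
        s, r = 12, 8
        u = rng.normal(0, np.sqrt(0.4), s)
        y = 5.0 + np.repeat(u, r) + rng.normal(0, 1.0, s * r)
        bundle = single_term_bundle(y, np.repeat(np.arange(s), r), s)
        vc = reml_estimate(bundle, None, tol=1e-12, max_iter=500)
        ybar = y.reshape(s, r).mean(axis=1)
        msb = r * np.sum((ybar - ybar.mean()) ** 2) / (s - 1)
        mse = np.sum((y.reshape(s, r) - ybar[:, None]) ** 2) / (s * (r - 1))
        assert vc.covs["group"][0, 0] == pytest.approx((msb - mse) / r, abs=1e-6)
        assert vc.sigma2_e == pytest.approx(mse, abs=1e-6)

    def test_em_likelihood_nondecreasing(self, small_sim):
        cfg, ped, effects, daily, covars = small_sim
        spec = ModelSpec("rrm", p=1, q=1, n=1, t_min=99, t_max=172)
        designs = build_design_matrices(spec, daily, covars, ped)
        vc = reml_estimate(designs, build_A_inverse(ped), algorithm="em",
                           tol=1e-6, max_iter=12)
        hist = np.asarray(vc.history)
        assert (np.diff(hist) > -1e-8).all()

    def test_A_and_H_identical_with_no_genotyped_animals(self, small_sim):
        from ssrrm import HBlendParams, build_H_inverse, subset_A
        cfg, ped, effects, daily, covars = small_sim
        spec = ModelSpec("rrm", p=1, q=1, n=1, t_min=99, t_max=172)
        designs = build_design_matrices(spec, daily, covars, ped)
        A_inv = build_A_inverse(ped)
        A22 = subset_A(build_A(ped), ped.ids[:2])
        H_inv = build_H_inverse(A_inv, A22, A22, HBlendParams(), [])
        va = reml_estimate(designs, A_inv, tol=1e-4, max_iter=15)
        vh = reml_estimate(designs, H_inv, tol=1e-4, max_iter=15)
        np.testing.assert_allclose(va.covs["additive"], vh.covs["additive"],
                                   atol=1e-10)
        assert va.loglik == pytest.approx(vh.loglik, abs=1e-8)

    def test_too_few_records_rejected(self):
        bundle = single_term_bundle([1.0, 2.0], [0, 1], 2)
        with pytest.raises(ValueError, match="fewer records"):
            reml_estimate(bundle, None)


class TestModelComparison:
    def test_bic_formula_spot_value(self):
        assert compute_bic(-100.0, 2, 100) == pytest.approx(209.2103404, abs=1e-6)

    def test_bic_zero_parameters(self):
        assert compute_bic(-50.0, 0, 10) == pytest.approx(100.0)

    def test_bic_increases_with_parameters(self):
        assert compute_bic(-100.0, 4, 50) > compute_bic(-100.0, 2, 50)

    def test_free_parameter_count(self):
        spec = ModelSpec("rrm", p=2, q=1, n=1)
        # vech sizes: 6 (Ka) + 3 (Kpe) + 3 (Klitter) + 1 residual
        assert n_free_parameters(spec) == 13

    def test_single_cell_grid_returned(self, small_sim):
        cfg, ped, effects, daily, covars = small_sim
        best, table = select_model_order([(1, 1, 1)], daily, covars, ped,
                                         build_A_inverse(ped), 99, 172,
                                         tol=1e-3, logl_tol=1e-2, max_iter=40)
        assert (best.p, best.q, best.n) == (1, 1, 1)
        assert len(table) == 1 and {"p", "q", "n", "converged",
                                    "bic"} <= set(table.columns)


class TestCrossModelConsistency:
    def test_order_zero_rrm_matches_animal_model_on_single_records(self):
        """With p=q=n=0 and one record per animal the RRM collapses to the
        animal model once the phi_0^2 = 1/2 basis factor is moved into the
        variances."""
        ped = make_pedigree([(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 2),
                             (5, 0, 0), (6, 5, 2)])
        rng = np.random.default_rng(1)
        daily = pd.DataFrame(dict(animal=ped.ids, age=120, ys=1, pen=1,
                                  intake=2.0 + rng.normal(0, 0.3, 6),
                                  body_weight=50.0, error_count=0))
        covars = pd.DataFrame(dict(animal=ped.ids, adg=0.9, bfa=12.0, sbw=50.0,
                                   mbw=25.0, adfi=daily["intake"]))
        spec0 = ModelSpec("rrm", p=0, q=0, n=0, t_min=99, t_max=172,
                          covariates=())
        spec_am = ModelSpec("animal", covariates=())
        A_inv = build_A_inverse(ped)
        s2a, s2l, s2p, s2e = 0.05, 0.01, 0.02, 0.04
        # animal model has no separate pe: fold it into the residual and
        # drop it from the order-0 RRM too for a clean comparison
        vc0 = VarianceComponents({"litter": [[2 * s2l]],
                                  "additive": [[2 * s2a]],
                                  "pe": [[1e-10]]}, s2e)
        vc_am = VarianceComponents({"litter": [[s2l]],
                                    "additive": [[s2a]]}, s2e)
        d0 = build_design_matrices(spec0, daily, covars, ped)
        dam = build_design_matrices(spec_am, daily, covars, ped)
        m0 = assemble_and_solve_mme(d0, A_inv, vc0)
        mam = assemble_and_solve_mme(dam, A_inv, vc_am)
        ebv0 = m0.coef("additive")[:, 0] * np.sqrt(0.5)
        np.testing.assert_allclose(ebv0, mam.coef("additive")[:, 0], atol=1e-6)
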