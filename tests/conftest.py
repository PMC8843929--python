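import numpy as np
import pandas as pd
import pytest

from ssrrm import (Pedigree, SimConfig, simulate_pedigree,
                   simulate_effects_and_phenotypes)
from ssrrm.preprocess import filter_test_window


def make_pedigree(rows):
    """rows: list of (id, sire, dam) or (id, sire, dam, litter)."""
    recs = []
    for r in rows:
        aid, sire, dam = r[:3]
        litter = r[3] if len(r) > 3 else aid
        recs.append(dict(id=aid, sire=sire, dam=dam,
                         birth_date=pd.Timestamp("2017-01-01"), litter=litter,
                         sex="M", genotyped=False, generation=0))
    return Pedigree(pd.DataFrame(recs))


@pytest.fixture(scope="session")
def small_sim():
    """A small but non-trivial simulated dataset shared across tests."""
    cfg = SimConfig(n_founders=16, n_generations=2, n_matings=8,
                    offspring_per_mating=3, n_snps=200, n_ys_levels=2,
                    n_pen_levels=2, window_range=(41, 46), seed=42)
    ped = simulate_pedigree(cfg)
    effects, daily, covars = simulate_effects_and_phenotypes(ped, cfg)
    daily = filter_test_window(daily)
    covars = covars[covars["animal"].isin(daily["animal"].unique())]
    return cfg, ped, effects, daily, covars


def dense_blup_oracle(designs, A_dense, vc):
    """Brute-force GLS/BLUP from the dense covariance V = ZGZ' + R."""
    X, y = designs.X, designs.y
    V = vc.sigma2_e * np.eye(len(y))
    parts = []
    for t in designs.terms:
        R = A_dense if t.name == "additive" else np.eye(t.n_levels)
        G = np.kron(R, vc.covs[t.name])
        Z = t.Z.toarray()
        V += Z @ G @ Z.T
        parts.append((Z, G))
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    resid = y - X @ beta
    sols = [beta] + [G @ Z.T @ Vi @ resid for Z, G in parts]
    return np.concatenate([s.ravel() for s in sols])
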