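"""From feeder visits to analysis-ready daily tables and covariates.

Pipeline order: visit aggregation (daily intake = sum of visit intakes,
daily body weight = mode of visit weights), removal of the first test week
(feeder adaptation), the minimum-test-length rule (>= 34 retained days),
an error-count correction of daily intake, and derivation of the per-animal
covariates (start/final weight, ADG, metabolic weight, ADFI).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "aggregate_visits",
    "filter_test_window",
    "adjust_for_error_counts",
    "derive_covariates",
]


def _weight_mode(values: np.ndarray) -> float:
    """Mode of measured weights; ties resolved as the mean of tied modes."""
    vals, counts = np.unique(values, return_counts=True)
    return float(vals[counts == counts.max()].mean())


def aggregate_visits(visits: pd.DataFrame) -> pd.DataFrame:
    """Collapse visit records to one row per animal-day.

    Daily intake is the sum of visit intakes, daily body weight the mode of
    visit weights (tied modes averaged), and the daily error count the
    number of flagged visits.
    """
    if visits.empty:
        return pd.DataFrame(columns=["animal", "age", "intake", "body_weight",
                                     "error_count", "test_start_age"])
    gb = visits.groupby(["animal", "age"], sort=True)
    aggs = {"intake": ("intake", "sum"),
            "body_weight": ("body_weight",
                            lambda s: _weight_mode(s.to_numpy()))}
    if "error" in visits.columns:
        aggs["error_count"] = ("error", "sum")
    for col in ("test_start_age", "ys", "pen"):
        if col in visits.columns:
            aggs[col] = (col, "first")
    daily = gb.agg(**aggs).reset_index()
    if "error_count" not in daily.columns:
        daily["error_count"] = 0
    daily["error_count"] = daily["error_count"].astype(int)
    return daily


def filter_test_window(daily: pd.DataFrame, min_days: int = 34,
                       adaptation_days: int = 7) -> pd.DataFrame:
    """Drop each animal's adaptation period, then short testers entirely.

    The adaptation cut is anchored on the per-animal test start age
    (``test_start_age`` column if present, else the first recorded age,
    which is then recorded so the operation is idempotent).  Animals with
    fewer than ``min_days`` remaining days are removed.
    """
    if min_days < 0 or adaptation_days < 0:
        raise ValueError("min_days and adaptation_days must be >= 0")
    if daily.empty:
        return daily.copy()
    out = daily.copy()
    if "test_start_age" not in out.columns:
        start = out.groupby("animal")["age"].transform("min")
        out["test_start_age"] = start
    keep = out["age"] >= out["test_start_age"] + adaptation_days
    out = out[keep]
    n_days = out.groupby("animal")["age"].transform("nunique")
    out = out[n_days >= min_days]
    return out.reset_index(drop=True)


def adjust_for_error_counts(daily: pd.DataFrame, covars: pd.DataFrame,
                            return_fit: bool = False):
    """Remove the estimated per-error intake perturbation from daily intake.

    Fits intake ~ intercept + error_count + ADG + body weight with a random
    animal intercept (linear mixed model, ML), then subtracts
    coefficient * error_count from each record, flooring the adjusted
    intake at zero.  With all error counts zero the data pass through
    unchanged.
    """
    out = daily.copy()
    if out.empty or (out["error_count"] == 0).all():
        return (out, 0.0) if return_fit else out
    data = out.merge(covars[["animal", "adg"]], on="animal", how="inner",
                     validate="m:1")
    if len(data) != len(out):
        raise ValueError("covariates missing for some phenotyped animals")
    X = np.column_stack([
        np.ones(len(data)),
        data["error_count"].to_numpy(dtype=float),
        data["adg"].to_numpy(dtype=float),
        data["body_weight"].to_numpy(dtype=float),
    ])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("error-adjustment design is rank deficient")
    import warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning
    model = sm.MixedLM(data["intake"].to_numpy(dtype=float), X,
                       groups=data["animal"].to_numpy())
    with warnings.catch_warnings():
        # the animal intercept variance often sits on the zero boundary
        # once ADG/body weight absorb the between-animal differences;
        # the fixed error-count coefficient is what this fit is for
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        fit = model.fit(reml=True, method="lbfgs", maxiter=200, disp=False)
    coef = float(fit.fe_params[1])
    out = data.drop(columns=["adg"])
    out["intake"] = np.maximum(out["intake"] - coef * out["error_count"], 0.0)
    out = out[daily.columns].reset_index(drop=True)
    return (out, coef) if return_fit else out


def derive_covariates(daily: pd.DataFrame, bfa: pd.Series | pd.DataFrame) -> pd.DataFrame:
    """Per-animal covariates from retained daily records.

    SBW/FBW are the body weights on the first/last retained day,
    ADG = (FBW - SBW)/(days - 1), MBW = mean(body weight)^0.75,
    ADFI = mean daily intake.  ``bfa`` maps animal -> back-fat (mm).
    """
    if isinstance(bfa, pd.DataFrame):
        bfa = bfa.set_index("animal")["bfa"]
    rows = []
    for animal, g in daily.sort_values(["animal", "age"]).groupby("animal"):
        ages = g["age"].to_numpy()
        if len(np.unique(ages)) < 2:
            raise ValueError(f"animal {animal} has a single retained day; "
                             "ADG undefined")
        bw = g["body_weight"].to_numpy(dtype=float)
        sbw, fbw = float(bw[0]), float(bw[-1])
        span = int(ages[-1] - ages[0])
        rows.append(dict(
            animal=animal,
            sbw=sbw, fbw=fbw,
            bfa=float(bfa.loc[animal]),
            adg=(fbw - sbw) / span,
            mbw=float(np.mean(bw) ** 0.75),
            on_age=int(ages[0]), off_age=int(ages[-1]),
            adfi=float(g["intake"].mean()),
        ))
    return pd.DataFrame(rows)
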