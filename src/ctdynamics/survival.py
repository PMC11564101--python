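"""Survival association: Kaplan–Meier, Cox proportional hazards, and
treatment-by-biomarker interaction tests.

Cox models use the partial likelihood with Efron's approximation for tied
event times (lifelines' default) and report hazard ratios with 95% CIs and
two-sided Wald p-values, with or without adjustment for baseline
covariates.  The interaction test fits treatment + biomarker + product
term and reports the product-term Wald test; continuous biomarkers enter
untransformed.  Proportional-hazards diagnostics are never used to gate a
fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

from .io import ValidationError

__all__ = [
    "KMGroupFit",
    "km_fit",
    "CoxResult",
    "cox_fit",
    "interaction_test",
]


@dataclass
class KMGroupFit:
    """Product-limit estimate for one group."""

    group: str
    n: int
    events: int
    median: float | None            # None = not reached
    median_ci: tuple[float | None, float | None]
    survival: pd.DataFrame          # columns: time, survival

    @property
    def median_reached(self) -> bool:
        return self.median is not None


def km_fit(times, events, groups=None) -> dict[str, KMGroupFit]:
    """Kaplan–Meier estimates per group.

    The median is the earliest time at which the estimated survival drops
    to 0.5 or below; when the curve never reaches 0.5 the median is
    reported as not reached (None).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValidationError("negative survival time")
    if groups is None:
        groups = np.array(["all"] * len(times))
    groups = np.asarray(groups)
    out: dict[str, KMGroupFit] = {}
    for g in sorted(pd.unique(groups).astype(str)):
        mask = groups.astype(str) == g
        if mask.sum() < 1:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        med = kmf.median_survival_time_
        med = None if np.isinf(med) else float(med)
        from lifelines.utils import median_survival_times
        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
        surv = kmf.survival_function_.reset_index()
        surv.columns = ["time", "survival"]
        out[g] = KMGroupFit(
            group=g, n=int(mask.sum()), events=int(events[mask].sum()),
            median=med,
            median_ci=(None if np.isinf(lo) else lo,
                       None if np.isinf(hi) else hi),
            survival=surv)
    return out


@dataclass
class CoxResult:
    """Cox PH fit summary: one row per coefficient."""

    summary: pd.DataFrame           # index covariate; HR, ci, z, p
    n: int
    events: int
    adjusted: bool
    converged: bool
    log_likelihood: float

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.summary.loc[covariate]
        return float(row["ci_low"]), float(row["ci_high"])

    def p(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])

    def z(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "z"])


def _fit_cox(df: pd.DataFrame, duration_col: str, event_col: str) -> CoxPHFitter:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    return cph


def cox_fit(times, events, covariates: pd.DataFrame,
            adjust: list[str] | None = None) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties, two-sided Wald tests).

    ``covariates`` holds the covariate(s) of interest; ``adjust`` names
    additional columns of ``covariates`` to include as adjustment terms
    (they must already be columns of the frame).  Raises a fit-failure
    signal on non-convergence or monotone likelihood.
    """
    covariates = pd.DataFrame(covariates).reset_index(drop=True)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 2:
        raise ValidationError("need at least 2 events for a Cox fit")
    for col in covariates.columns:
        if covariates[col].nunique() <= 1:
            raise ValidationError(f"constant covariate {col!r}")
    df = covariates.copy()
    df["_time"], df["_event"] = times, events
    try:
        cph = _fit_cox(df, "_time", "_event")
    except (ConvergenceError, Exception) as exc:  # monotone likelihood etc.
        raise ValidationError(f"Cox fit failed: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame({
        "coef": s["coef"],
        "hr": s["exp(coef)"],
        "ci_low": s["exp(coef) lower 95%"],
        "ci_high": s["exp(coef) upper 95%"],
        "z": s["z"],
        "p": s["p"],
    })
    return CoxResult(summary=summary, n=len(df), events=int(events.sum()),
                     adjusted=bool(adjust), converged=True,
                     log_likelihood=float(cph.log_likelihood_))


def interaction_test(times, events, treatment, biomarker,
                     adjust: pd.DataFrame | None = None) -> dict:
    """Wald test of a treatment x biomarker product term in a Cox model.

    The model contains treatment, biomarker and their product; the
    reported HR/CI/p belong to the product term.  The biomarker may be
    binary (e.g. a median-split group) or continuous (used untransformed).
    """
    treatment = np.asarray(treatment, dtype=float)
    biomarker = np.asarray(biomarker, dtype=float)
    df = pd.DataFrame({
        "treatment": treatment,
        "biomarker": biomarker,
        "interaction": treatment * biomarker,
    })
    if adjust is not None:
        adjust = pd.DataFrame(adjust).reset_index(drop=True)
        for col in adjust.columns:
            df[col] = adjust[col].to_numpy()
    res = cox_fit(times, events, df)
    row = res.summary.loc["interaction"]
    return {
        "hr": float(row["hr"]),
        "ci_low": float(row["ci_low"]),
        "ci_high": float(row["ci_high"]),
        "log_hr": float(row["coef"]),
        "z": float(row["z"]),
        "p_value": float(row["p"]),
        "n": res.n,
        "events": res.events,
        "adjusted": adjust is not None,
    }
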