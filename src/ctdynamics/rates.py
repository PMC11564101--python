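"""Mutation-acquisition rates and their modelling.

Each paired patient contributes a count of acquired-status alterations and
an exposure (time on treatment, months); the per-patient rate is their
ratio, assuming a constant acquisition rate over treatment.  Two models sit
on top of the counts:

* a K-component Poisson mixture with exposure offsets,
  ``count_i ~ Poisson(lambda_k * t_i)``, fitted by EM, used to partition
  patients into low/medium/high-rate subgroups (K defaults to 3);
* a negative-binomial regression of counts on treatment-arm indicators with
  ``log(t_i)`` offsets, whose exponentiated coefficients are arm rate
  ratios versus a reference arm.  NB absorbs the between-patient rate
  heterogeneity that the mixture models explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln, logsumexp

from .io import ValidationError

__all__ = [
    "compute_rates",
    "zero_rate_display",
    "PoissonMixtureFit",
    "fit_poisson_mixture",
    "poisson_mixture_bic_table",
    "compare_rates_nb",
]


def compute_rates(status_records: pd.DataFrame,
                  patients: pd.DataFrame) -> pd.DataFrame:
    """Acquired-alteration counts and per-month rates per paired patient.

    Every patient in ``patients`` contributes a row (zero counts included);
    the exposure is ``time_on_treatment_months`` and must be positive.
    """
    counts = (status_records[status_records["status"] == "acquired"]
              .groupby("patient_id").size())
    rows = []
    for _, pat in patients.iterrows():
        months = pat["time_on_treatment_months"]
        if not months > 0:
            raise ValidationError(
                f"patient {pat['patient_id']}: nonpositive exposure")
        n_acq = int(counts.get(pat["patient_id"], 0))
        rows.append({
            "patient_id": pat["patient_id"],
            "arm": pat["arm"],
            "acquired_count": n_acq,
            "exposure_months": float(months),
            "rate_per_month": n_acq / months,
        })
    return pd.DataFrame(rows)


def zero_rate_display(rates, zero_code: float | None = None) -> np.ndarray:
    """Display transform mapping zero rates to half the smallest nonzero rate.

    Only for plotting on log scales; never used in modelling.
    """
    rates = np.asarray(rates, dtype=float)
    nonzero = rates[rates > 0]
    if zero_code is None:
        if nonzero.size == 0:
            return rates.copy()
        zero_code = float(nonzero.min()) / 2.0
    out = rates.copy()
    out[out == 0] = zero_code
    return out


# ---------------------------------------------------------------------------
# Poisson mixture with exposure offsets
# ---------------------------------------------------------------------------

@dataclass
class PoissonMixtureFit:
    """EM fit of a K-component Poisson mixture on counts with offsets."""

    K: int
    weights: np.ndarray           # (K,), simplex
    rates: np.ndarray             # (K,), per month, sorted ascending
    responsibilities: np.ndarray  # (n, K), rows sum to 1
    assignments: np.ndarray       # (n,), argmax component labels
    loglik: float
    converged: bool
    n_iter: int
    degenerate: bool = False      # all-zero counts with K > 1

    def bic(self, n: int | None = None) -> float:
        n = n if n is not None else self.responsibilities.shape[0]
        n_params = 2 * self.K - 1
        return -2.0 * self.loglik + n_params * np.log(n)


def _mixture_loglik(counts, exposures, weights, rates):
    # log f_ik = y log(lam_k t_i) - lam_k t_i - log(y!)
    lam_t = np.outer(exposures, rates)               # (n, K)
    with np.errstate(divide="ignore"):
        log_f = (counts[:, None] * np.log(lam_t) - lam_t
                 - gammaln(counts + 1.0)[:, None])
    log_f = np.where((lam_t == 0) & (counts[:, None] == 0), 0.0, log_f)
    log_mix = log_f + np.log(weights)[None, :]
    per_obs = logsumexp(log_mix, axis=1)
    return float(per_obs.sum()), log_mix - per_obs[:, None]


def fit_poisson_mixture(observations: pd.DataFrame,
                        K: int = 3,
                        n_restarts: int = 20,
                        seed: int | None = 0,
                        max_iter: int = 2000,
                        tol: float = 1e-8) -> PoissonMixtureFit:
    """Fit ``count_i ~ Poisson(lambda_k * t_i)`` by EM, best of restarts.

    Initialisation places component rates at quantiles of the observed
    per-patient rates, jittered multiplicatively across restarts.  The
    log-likelihood is asserted nondecreasing at every EM iteration, and
    components are reported in ascending rate order (low/medium/high for
    K = 3).  K = 1 reduces to the closed-form pooled MLE
    ``sum(counts)/sum(exposures)``.
    """
    counts = np.asarray(observations["acquired_count"], dtype=float)
    exposures = np.asarray(observations["exposure_months"], dtype=float)
    n = counts.size
    if K < 1:
        raise ValidationError("K must be >= 1")
    if n < K:
        raise ValidationError(f"need at least K={K} observations, got {n}")
    if (exposures <= 0).any():
        raise ValidationError("exposures must be positive")

    degenerate = bool(counts.sum() == 0 and K > 1)
    if degenerate:
        warnings.warn("all counts are zero; mixture with K > 1 is degenerate",
                      stacklevel=2)

    if K == 1:
        lam = counts.sum() / exposures.sum()
        ll, _ = _mixture_loglik(counts, exposures, np.ones(1), np.array([lam]))
        return PoissonMixtureFit(
            K=1, weights=np.ones(1), rates=np.array([lam]),
            responsibilities=np.ones((n, 1)),
            assignments=np.zeros(n, dtype=int),
            loglik=ll, converged=True, n_iter=0, degenerate=False)

    rng = np.random.default_rng(seed)
    obs_rates = counts / exposures
    pooled = max(counts.sum() / exposures.sum(), 1e-8)
    quantiles = np.quantile(obs_rates, (np.arange(K) + 0.5) / K)
    quantiles = np.maximum(quantiles, 1e-3 * pooled)

    best = None
    for restart in range(max(1, n_restarts)):
        jitter = rng.lognormal(0.0, 0.5, size=K) if restart else np.ones(K)
        rates = np.sort(quantiles * jitter)
        weights = np.full(K, 1.0 / K)
        prev_ll = -np.inf
        converged = False
        for it in range(1, max_iter + 1):
            ll, log_resp = _mixture_loglik(counts, exposures, weights, rates)
            assert ll >= prev_ll - 1e-6 * (1.0 + abs(ll)), \
                "EM log-likelihood decreased"
            resp = np.exp(log_resp)
            weights = resp.mean(axis=0)
            denom = resp.T @ exposures
            rates = np.where(denom > 0, (resp.T @ counts) / denom, 0.0)
            rates = np.maximum(rates, 1e-12)
            if ll - prev_ll < tol * (1.0 + abs(ll)):
                converged = True
                prev_ll = ll
                break
            prev_ll = ll
        ll, log_resp = _mixture_loglik(counts, exposures, weights, rates)
        if best is None or ll > best[0]:
            best = (ll, weights, rates, np.exp(log_resp), converged, it)

    ll, weights, rates, resp, converged, n_iter = best
    order = np.argsort(rates)
    rates, weights, resp = rates[order], weights[order], resp[:, order]
    return PoissonMixtureFit(
        K=K, weights=weights, rates=rates, responsibilities=resp,
        assignments=resp.argmax(axis=1), loglik=ll,
        converged=converged, n_iter=n_iter, degenerate=degenerate)


def poisson_mixture_bic_table(observations: pd.DataFrame,
                              k_values=(1, 2, 3, 4, 5),
                              n_restarts: int = 20,
                              seed: int | None = 0) -> pd.DataFrame:
    """BIC over candidate component counts (model-choice diagnostic)."""
    rows = []
    n = len(observations)
    for k in k_values:
        if n < k:
            continue
        fit = fit_poisson_mixture(observations, K=k, n_restarts=n_restarts,
                                  seed=seed)
        rows.append({"K": k, "loglik": fit.loglik, "bic": fit.bic(n)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# negative-binomial arm comparison
# ---------------------------------------------------------------------------

def compare_rates_nb(observations: pd.DataFrame,
                     reference_arm: str = "control") -> dict:
    """Arm rate ratios from NB regression of counts with log-exposure offsets.

    Returns a mapping ``arm -> {rate_ratio, ci_low, ci_high, p_value}`` for
    every non-reference arm, plus the model family used (``negbin``, or
    ``poisson`` when the NB dispersion fit fails, flagged via ``fallback``).
    """
    arms = sorted(observations["arm"].unique())
    if reference_arm not in arms:
        raise ValidationError(f"reference arm {reference_arm!r} not present")
    if len(arms) < 2:
        raise ValidationError("need at least two arms")
    for arm in arms:
        if (observations["arm"] == arm).sum() < 2:
            raise ValidationError(f"arm {arm!r} has fewer than 2 patients")

    others = [a for a in arms if a != reference_arm]
    X = np.column_stack([np.ones(len(observations))] + [
        (observations["arm"] == a).to_numpy(dtype=float) for a in others])
    y = observations["acquired_count"].to_numpy(dtype=float)
    exposure = observations["exposure_months"].to_numpy(dtype=float)

    family, fallback = "negbin", False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.NegativeBinomial(y, X, exposure=exposure)
            res = model.fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError("NB did not converge")
        params, conf = res.params, res.conf_int()
        pvals = res.pvalues
    except Exception:
        family, fallback = "poisson", True
        model = sm.GLM(y, X, family=sm.families.Poisson(),
                       exposure=exposure)
        res = model.fit()
        params, conf = res.params, res.conf_int()
        pvals = res.pvalues

    out = {"family": family, "fallback": fallback, "reference": reference_arm,
           "arms": {}}
    for j, arm in enumerate(others, start=1):
        out["arms"][arm] = {
            "rate_ratio": float(np.exp(params[j])),
            "ci_low": float(np.exp(conf[j][0])),
            "ci_high": float(np.exp(conf[j][1])),
            "p_value": float(pvals[j]),
        }
    return out
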