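"""Model-based causal mediation with quasi-Bayesian Monte Carlo inference.

Does methylation at a CpG mediate the exposure→outcome association, and
what fraction of the total effect runs through it? Two regression models
are fitted — the mediator model (CpG ~ exposure + covariates, OLS) and
the outcome model (outcome ~ exposure + CpG + covariates, OLS or
logistic) — both with robust (sandwich) coefficient covariances. Coefficient
vectors are then drawn from the normal approximation to their sampling
distribution, and for each draw the average causal mediation effect
(ACME), average direct effect (ADE), and total effect (TE) are computed
from potential-outcome contrasts. Point estimates are means over draws,
intervals are 2.5/97.5 percentiles, and P values are simulation-based
two-sided tail probabilities.

In the fully linear case with no exposure×mediator interaction the
per-draw identities ACME = a·b, ADE = c, and TE = ACME + ADE hold exactly
(product-of-coefficients form). Binary outcomes are handled on the
probability (risk-difference) scale by simulating mediator potential
values and pushing them through the logistic outcome model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MediationModelFit",
    "MediationRecord",
    "fit_mediation_models",
    "quasi_bayesian_mediate",
    "proportion_mediated",
]

DEFAULT_N_DRAWS = 2000


@dataclass
class MediationModelFit:
    """Fitted mediator and outcome models with robust covariances."""

    exposure: str
    mediator: str
    outcome: str
    covariates: list[str]
    outcome_model: str  # linear | logistic
    med_params: np.ndarray
    med_cov: np.ndarray
    med_sigma2: float
    out_params: np.ndarray
    out_cov: np.ndarray
    med_exog_names: list[str]
    out_exog_names: list[str]
    total_params: np.ndarray
    total_cov: np.ndarray
    n: int
    #: design of the mediator model (for simulating mediator potential values)
    med_exog: np.ndarray = field(repr=False, default=None)
    out_exog: np.ndarray = field(repr=False, default=None)

    @property
    def beta_a(self) -> float:
        """Exposure coefficient of the mediator model."""
        return float(self.med_params[self.med_exog_names.index(self.exposure)])

    @property
    def beta_b(self) -> float:
        """Mediator coefficient of the outcome model (given exposure)."""
        return float(self.out_params[self.out_exog_names.index(self.mediator)])

    @property
    def direct_effect_coef(self) -> float:
        """Exposure coefficient of the outcome model containing the mediator."""
        return float(self.out_params[self.out_exog_names.index(self.exposure)])

    @property
    def total_effect_coef(self) -> float:
        """Exposure coefficient of the outcome model without the mediator."""
        return float(self.total_params[1])


def _robust_fit(y: np.ndarray, X: pd.DataFrame, model: str):
    if model == "linear":
        res = sm.OLS(y, X).fit(cov_type="HC1")
    else:
        try:
            res = sm.Logit(y, X).fit(disp=0)
        except Exception as err:  # PerfectSeparationError and kin
            raise ValueError(f"logistic outcome model failed: {err}") from err
        if not np.isfinite(res.bse).all() or res.bse.max() > 1e3:
            raise ValueError("separation suspected in logistic outcome model (unstable fit)")
        res = sm.Logit(y, X).fit(disp=0, cov_type="HC1")
    return res


def fit_mediation_models(
    data: pd.DataFrame,
    exposure: str,
    mediator_cpg: str,
    outcome: str,
    covariates: list[str] | None = None,
    outcome_model: str = "linear",
) -> MediationModelFit:
    """Fit the mediator and outcome regressions on complete cases."""
    covariates = list(covariates or [])
    if outcome_model not in ("linear", "logistic"):
        raise ValueError(f"outcome_model must be 'linear' or 'logistic', got {outcome_model!r}")
    cols = [exposure, mediator_cpg, outcome] + covariates
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"columns missing from data: {missing}")
    d = data[cols].dropna()
    n = len(d)
    n_out_params = 3 + len(covariates)  # intercept + exposure + mediator + covariates
    if n < n_out_params + 1:
        raise ValueError(f"too few complete cases ({n}) for mediation models")
    if float(d[mediator_cpg].var()) == 0.0:
        raise ValueError("mediator has zero variance")

    X_med = sm.add_constant(d[[exposure] + covariates])
    med = sm.OLS(d[mediator_cpg].to_numpy(float), X_med).fit(cov_type="HC1")
    X_out = sm.add_constant(d[[exposure, mediator_cpg] + covariates])
    out = _robust_fit(d[outcome].to_numpy(float), X_out, outcome_model)
    X_tot = sm.add_constant(d[[exposure] + covariates])
    tot = _robust_fit(d[outcome].to_numpy(float), X_tot, outcome_model)

    return MediationModelFit(
        exposure=exposure,
        mediator=mediator_cpg,
        outcome=outcome,
        covariates=covariates,
        outcome_model=outcome_model,
        med_params=np.asarray(med.params),
        med_cov=np.asarray(med.cov_params()),
        med_sigma2=float(med.mse_resid),
        out_params=np.asarray(out.params),
        out_cov=np.asarray(out.cov_params()),
        med_exog_names=list(X_med.columns),
        out_exog_names=list(X_out.columns),
        total_params=np.asarray(tot.params),
        total_cov=np.asarray(tot.cov_params()),
        n=n,
        med_exog=X_med.to_numpy(float),
        out_exog=X_out.to_numpy(float),
    )


@dataclass
class MediationRecord:
    acme: float
    ade: float
    total_effect: float
    prop_mediated: float
    acme_ci: tuple[float, float]
    ade_ci: tuple[float, float]
    total_effect_ci: tuple[float, float]
    prop_mediated_ci: tuple[float, float]
    acme_pval: float
    ade_pval: float
    total_effect_pval: float
    n_draws: int
    seed: int
    outcome_model: str
    unstable_proportion: bool = False
    #: per-draw quantities kept for downstream summaries
    draws: dict = field(default_factory=dict, repr=False)


def _sim_pval(draws: np.ndarray) -> float:
    lo = float(np.mean(draws <= 0.0))
    hi = float(np.mean(draws >= 0.0))
    return min(1.0, 2.0 * min(lo, hi))


def _mvn_draws(rng: np.random.Generator, mean: np.ndarray, cov: np.ndarray, n: int) -> np.ndarray:
    try:
        chol = np.linalg.cholesky(cov + 1e-14 * np.eye(len(cov)) * np.trace(cov))
    except np.linalg.LinAlgError as err:
        raise ValueError("singular coefficient covariance; cannot draw") from err
    z = rng.standard_normal((n, len(mean)))
    return mean + z @ chol.T

def quasi_bayesian_mediate(
    fit: MediationModelFit,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
) -> MediationRecord:
    """Propagate coefficient uncertainty into ACME/ADE/TE by simulation.

    Coefficient vectors of the two models are drawn independently from
    normal approximations with the robust covariances. For the linear
    outcome model the per-draw effects are the exact potential-outcome
    contrasts ACME = a·b and ADE = c (averaging over mediator noise has
    no effect in a linear model), so ACME + ADE = TE holds per draw. For
    the logistic model, mediator potential values are simulated and the
    contrasts averaged over the sample and both exposure arms, on the
    probability scale.
    """
    if n_draws < 100:
        raise ValueError(f"n_draws must be >= 100, got {n_draws}")
    rng = np.random.default_rng(seed)
    med_draws = _mvn_draws(rng, fit.med_params, fit.med_cov, n_draws)
    out_draws = _mvn_draws(rng, fit.out_params, fit.out_cov, n_draws)

    i_a = fit.med_exog_names.index(fit.exposure)
    i_c = fit.out_exog_names.index(fit.exposure)
    i_b = fit.out_exog_names.index(fit.mediator)

    if fit.outcome_model == "linear":
        acme_d = med_draws[:, i_a] * out_draws[:, i_b]
        ade_d = out_draws[:, i_c]
        te_d = acme_d + ade_d
    else:
        acme_d, ade_d, te_d = _logistic_contrasts(fit, med_draws, out_draws, rng, i_a, i_c, i_b)

    with np.errstate(divide="ignore", invalid="ignore"):
        prop_d = np.where(te_d != 0, acme_d / te_d, np.nan)

    def ci(d):
        return (float(np.percentile(d, 2.5)), float(np.percentile(d, 97.5)))

    te_ci = ci(te_d)
    unstable = te_ci[0] <= 0.0 <= te_ci[1]
    record = MediationRecord(
        acme=float(acme_d.mean()),
        ade=float(ade_d.mean()),
        total_effect=float(te_d.mean()),
        prop_mediated=float(np.nanmedian(prop_d)),
        acme_ci=ci(acme_d),
        ade_ci=ci(ade_d),
        total_effect_ci=te_ci,
        prop_mediated_ci=ci(prop_d[np.isfinite(prop_d)]),
        acme_pval=_sim_pval(acme_d),
        ade_pval=_sim_pval(ade_d),
        total_effect_pval=_sim_pval(te_d),
        n_draws=n_draws,
        seed=seed,
        outcome_model=fit.outcome_model,
        unstable_proportion=bool(unstable),
        draws={"acme": acme_d, "ade": ade_d, "total_effect": te_d, "prop_mediated": prop_d},
    )
    return record


def _logistic_contrasts(fit, med_draws, out_draws, rng, i_a, i_c, i_b):
    """Simulated potential-outcome contrasts on the probability scale."""
    n = fit.med_exog.shape[0]
    n_draws = med_draws.shape[0]
    sigma = np.sqrt(fit.med_sigma2)
    X_med0 = fit.med_exog.copy()
    X_med1 = fit.med_exog.copy()
    X_med0[:, i_a] = 0.0
    X_med1[:, i_a] = 1.0
    acme = np.empty(n_draws)
    ade = np.empty(n_draws)
    te = np.empty(n_draws)
    expit = lambda x: 1.0 / (1.0 + np.exp(-x))
    X_out = fit.out_exog
    for d in range(n_draws):
        g = med_draws[d]
        th = out_draws[d]
        eps = rng.standard_normal(n) * sigma
        m0 = X_med0 @ g + eps
        m1 = X_med1 @ g + eps

        def p(t, m):
            Xo = X_out.copy()
            Xo[:, i_c] = t
            Xo[:, i_b] = m
            return expit(Xo @ th)

        # average over both exposure arms for ACME and ADE
        acme[d] = 0.5 * ((p(1, m1) - p(1, m0)).mean() + (p(0, m1) - p(0, m0)).mean())
        ade[d] = 0.5 * ((p(1, m1) - p(0, m1)).mean() + (p(1, m0) - p(0, m0)).mean())
        te[d] = (p(1, m1) - p(0, m0)).mean()
    return acme, ade, te


def proportion_mediated(record: MediationRecord) -> dict:
    """Proportion of the total effect carried by the mediator.

    Summarized as the median of the per-draw ratio ACME/TE with a
    percentile interval (ratios of means are unstable when the total
    effect is near zero). Also reports the ratio-of-means variant. An
    instability flag is raised when the TE interval covers zero; a TE
    point estimate of exactly zero makes the proportion undefined.
    """
    if record.total_effect == 0.0:
        raise ValueError("total effect is exactly 0: proportion mediated undefined")
    prop_d = record.draws["prop_mediated"]
    finite = prop_d[np.isfinite(prop_d)]
    return {
        "prop_mediated": float(np.median(finite)),
        "ci": (float(np.percentile(finite, 2.5)), float(np.percentile(finite, 97.5))),
        "ratio_of_means": float(record.acme / record.total_effect),
        "unstable": bool(record.unstable_proportion or np.sign(record.acme) != np.sign(record.total_effect)),
    }
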