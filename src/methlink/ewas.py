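"""Per-cohort epigenome-wide association models.

Each CpG's beta value is regressed on the exposure plus covariates by
ordinary least squares; two-sided P values come from the t distribution
with the residual degrees of freedom. Because the design matrix is shared
across CpGs, the fits are computed for all CpGs at once from a single QR
decomposition of the design.

Variants: the main maternal-smoking model, a never-smoker restriction, a
standardized dose-response model (SD of methylation per three additional
cigarettes/day), and the paternal-smoking negative control with a
paternal-adjusted maternal model.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CohortBundle

logger = logging.getLogger(__name__)

__all__ = [
    "fit_ewas",
    "restrict_never_smokers",
    "fit_dose_response",
    "fit_negative_control",
]

EWAS_COLUMNS = ["cpg_id", "beta", "se", "pval", "n", "model_tag"]


def _design_matrix(covariates: pd.DataFrame, exposure: str, covariate_columns: list[str]) -> tuple[np.ndarray, list[str]]:
    cols = [exposure] + [c for c in covariate_columns if c != exposure]
    missing = [c for c in cols if c not in covariates.columns]
    if missing:
        raise ValueError(f"columns not present in covariate table: {missing}")
    X = np.column_stack(
        [np.ones(len(covariates))] + [covariates[c].to_numpy(float) for c in cols]
    )
    return X, ["(intercept)"] + cols


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    # pivoted QR localizes the offending (linearly dependent) columns
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    dependent = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if dependent:
        raise ValueError(f"rank-deficient design; offending columns: {dependent}")


def ols_many(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """OLS of each column of Y on X.

    Returns (coef, se, pval, df) where coef and se have shape
    (n_params, n_outcomes) and pval are two-sided t-tail probabilities.
    """
    n, p = X.shape
    df = n - p
    if df < 2:
        raise ValueError(f"complete cases ({n}) must exceed parameters ({p}) + 2")
    q, r = np.linalg.qr(X)
    coef = np.linalg.solve(r, q.T @ Y)
    resid = Y - X @ coef
    sigma2 = (resid**2).sum(axis=0) / df
    rinv = np.linalg.inv(r)
    xtx_inv_diag = (rinv**2).sum(axis=1)
    se = np.sqrt(np.outer(xtx_inv_diag, sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = coef / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), df)
    return coef, se, pval, df


def _fit_records(
    meth: pd.DataFrame,
    covariates: pd.DataFrame,
    exposure: str,
    covariate_columns: list[str],
    model_tag: str,
    standardize: bool = False,
    scale: float = 1.0,
) -> pd.DataFrame:
    X_full, names = _design_matrix(covariates, exposure, covariate_columns)
    # complete cases over the design; per-CpG methylation missingness below
    row_ok = np.isfinite(X_full).all(axis=1)
    n_dropped = int((~row_ok).sum())
    if n_dropped:
        logger.info("%s: dropped %d incomplete samples", model_tag, n_dropped)
    X = X_full[row_ok]
    _check_rank(X, names)
    if np.var(X[:, 1]) == 0.0:
        raise ValueError(f"exposure column {exposure!r} has zero variance")

    Y = meth.to_numpy(float)[row_ok]
    records = []
    sd = Y.std(axis=0, ddof=1)
    zero_var = sd == 0.0
    if zero_var.any():
        logger.info("%s: skipped %d zero-variance CpGs", model_tag, int(zero_var.sum()))
    if standardize:
        Ys = np.where(zero_var, np.nan, (Y - Y.mean(axis=0)) / np.where(zero_var, 1.0, sd))
    else:
        Ys = Y

    col_complete = np.isfinite(Ys).all(axis=0)
    usable = col_complete & ~zero_var
    if usable.any():
        coef, se, pval, _ = ols_many(Ys[:, usable], X)
        ids = meth.columns[usable]
        records.append(
            pd.DataFrame(
                {
                    "cpg_id": ids,
                    "beta": coef[1] * scale,
                    "se": se[1] * scale,
                    "pval": pval[1],
                    "n": X.shape[0],
                    "model_tag": model_tag,
                }
            )
        )
    # CpGs with missing values: fit per CpG on their own complete cases
    ragged = np.flatnonzero(~col_complete & ~zero_var)
    for j in ragged:
        ok = np.isfinite(Ys[:, j])
        if ok.sum() < X.shape[1] + 2:
            logger.info("%s: skipped %s (too few complete cases)", model_tag, meth.columns[j])
            continue
        coef, se, pval, _ = ols_many(Ys[ok][:, [j]], X[ok])
        records.append(
            pd.DataFrame(
                {
                    "cpg_id": [meth.columns[j]],
                    "beta": coef[1] * scale,
                    "se": se[1] * scale,
                    "pval": pval[1],
                    "n": int(ok.sum()),
                    "model_tag": model_tag,
                }
            )
        )
    if not records:
        return pd.DataFrame(columns=EWAS_COLUMNS)
    out = pd.concat(records, ignore_index=True)
    fitted = set(out["cpg_id"])
    order = [c for c in meth.columns if c in fitted]
    return out.set_index("cpg_id").loc[order].reset_index()


def fit_ewas(
    bundle: CohortBundle,
    exposure_column: str = "maternal_smoking",
    covariate_columns: list[str] | None = None,
    model_tag: str | None = None,
) -> pd.DataFrame:
    """Association of each CpG's methylation with the exposure.

    Returns a table with one row per CpG: ``cpg_id, beta, se, pval, n,
    model_tag``. Effects are in beta-value units per exposure unit.
    """
    covariate_columns = list(covariate_columns or [])
    tag = model_tag or f"ewas_{exposure_column}"
    return _fit_records(bundle.methylation, bundle.covariates, exposure_column, covariate_columns, tag)


def restrict_never_smokers(bundle: CohortBundle) -> CohortBundle:
    """Subset to participants who never smoked regularly themselves.

    The own-smoking covariate is dropped from the returned bundle since it
    is constant in the subset (and must not be adjusted for downstream).
    """
    if "own_smoking" not in bundle.covariates.columns:
        raise ValueError("own_smoking column not present")
    keep = bundle.covariates.index[bundle.covariates["own_smoking"] == 0]
    if len(keep) == 0:
        raise ValueError("no never-smokers in cohort; empty subset")
    sub = bundle.subset(keep)
    sub.covariates = sub.covariates.drop(columns=["own_smoking"])
    return sub


def fit_dose_response(
    bundle: CohortBundle,
    covariate_columns: list[str] | None = None,
    cigarettes_per_unit: float = 3.0,
    dose_column: str = "cigs_per_day",
) -> pd.DataFrame:
    """Dose-response model: SD of methylation per ``cigarettes_per_unit``
    additional cigarettes smoked per day.

    Methylation is standardized to zero mean and unit SD per CpG; the OLS
    slope per cigarette/day is scaled to the per-three-cigarette
    convention. The full cohort, including unexposed (dose 0) mothers, is
    analyzed.
    """
    covariate_columns = list(covariate_columns or [])
    if dose_column not in bundle.covariates.columns:
        raise ValueError(f"{dose_column} column not present")
    if np.var(bundle.covariates[dose_column].to_numpy(float)) == 0.0:
        raise ValueError("zero-variance dose: all cigarettes/day values identical")
    return _fit_records(
        bundle.methylation,
        bundle.covariates,
        dose_column,
        covariate_columns,
        model_tag=f"dose_per{cigarettes_per_unit:g}",
        standardize=True,
        scale=cigarettes_per_unit,
    )


def fit_negative_control(
    bundle: CohortBundle,
    covariate_columns: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Negative-control comparison of maternal and paternal smoking.

    Three models per CpG: exposure = maternal smoking; exposure = paternal
    smoking; exposure = maternal smoking with paternal smoking added as a
    covariate. Under a shared-environment-only paternal path, paternal
    effects should be much smaller than maternal ones and the
    paternal-adjusted maternal estimates close to the unadjusted ones.
    """
    covariate_columns = list(covariate_columns or [])
    cov = bundle.covariates
    if "paternal_smoking" not in cov.columns:
        raise ValueError("paternal_smoking column not present")
    pat = cov["paternal_smoking"].to_numpy(float)
    mat = cov["maternal_smoking"].to_numpy(float)
    if np.var(pat) == 0.0:
        raise ValueError("paternal smoking indicator is constant")
    r = np.corrcoef(mat, pat)[0, 1]
    if abs(r) > 1.0 - 1e-12:
        raise ValueError(
            "maternal and paternal smoking are perfectly collinear; "
            "negative control uninformative"
        )
    base = [c for c in covariate_columns if c not in ("maternal_smoking", "paternal_smoking")]
    return {
        "maternal": _fit_records(bundle.methylation, cov, "maternal_smoking", base, "ewas_maternal"),
        "paternal": _fit_records(bundle.methylation, cov, "paternal_smoking", base, "ewas_paternal"),
        "maternal_adj_paternal": _fit_records(
            bundle.methylation, cov, "maternal_smoking", base + ["paternal_smoking"],
            "ewas_maternal_adj_paternal",
        ),
    }
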