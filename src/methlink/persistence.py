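"""Longitudinal persistence of exposure-associated methylation.

Two-stage procedure for cohorts measured at two timepoints:

1. :func:`residualize` regresses methylation at each timepoint on the
   technical and white-blood-cell covariates and keeps the residuals.
2. :func:`fit_gls_persistence` stacks both timepoints and fits, per CpG,

       resid ~ exposure + timepoint + exposure:timepoint + covariates

   by iterated feasible generalized least squares with an unstructured
   2x2 within-individual error covariance (two timepoint variances and
   one cross-timepoint correlation). The exposure effect at timepoint 2
   equals the timepoint-1 effect plus the interaction coefficient, and
   the test of equal effects at the two timepoints is the test that the
   interaction is zero.

Individuals observed at only one timepoint are retained (unbalanced
panel); their error block is the corresponding 1x1 variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "residualize",
    "fit_gls_persistence",
    "PersistenceRecord",
    "technical_covariate_columns",
]


def technical_covariate_columns(covariates: pd.DataFrame) -> list[str]:
    """Technical-PC and cell-proportion columns, dropping one cell type.

    Cell proportions sum to 1, so one column (the last, by convention the
    rarest type) must be left out as the reference to keep a design with
    an intercept full rank.
    """
    tpcs = [c for c in covariates.columns if c.startswith("tpc")]
    cells = sorted(c for c in covariates.columns if c.startswith("cell_"))
    return tpcs + cells[:-1]


def residualize(methylation: pd.DataFrame, covariates: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Per-CpG OLS residuals of methylation on the given covariates.

    With an empty covariate list this is plain centering. Residual columns
    are mean-zero and orthogonal to every covariate column.
    """
    columns = list(columns or [])
    missing = [c for c in columns if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate columns missing: {missing}")
    X = np.column_stack(
        [np.ones(len(methylation))] + [covariates.loc[methylation.index, c].to_numpy(float) for c in columns]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient residualization design")
    Y = methylation.to_numpy(float)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    return pd.DataFrame(resid, index=methylation.index, columns=methylation.columns)


@dataclass
class PersistenceRecord:
    cpg_id: str
    beta_t1: float
    se_t1: float
    beta_t2: float
    se_t2: float
    interaction_beta: float
    interaction_se: float
    equality_pval: float
    resid_var_t1: float
    resid_var_t2: float
    resid_corr: float
    n_individuals: int
    n_paired: int
    converged: bool


def _stack_design(
    exposure: pd.Series,
    covariates: dict[str, pd.DataFrame] | None,
    covariate_columns: list[str],
    ids_t: dict[str, pd.Index],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Long-format design over both timepoints.

    Returns (X, time_index, individual_index) with columns
    [1, exposure, time, exposure x time, covariates...].
    """
    rows_X, rows_t, rows_i = [], [], []
    all_ids = ids_t["t1"].union(ids_t["t2"])
    id_pos = {s: k for k, s in enumerate(all_ids)}
    for t_lab, t_val in (("t1", 0.0), ("t2", 1.0)):
        ids = ids_t[t_lab]
        e = exposure.loc[ids].to_numpy(float)
        block = [np.ones(len(ids)), e, np.full(len(ids), t_val), e * t_val]
        for c in covariate_columns:
            tab = covariates[t_lab] if covariates else None
            if tab is None or c not in tab.columns:
                raise ValueError(f"covariate column {c!r} missing at {t_lab}")
            block.append(tab.loc[ids, c].to_numpy(float))
        rows_X.append(np.column_stack(block))
        rows_t.append(np.full(len(ids), 0 if t_lab == "t1" else 1))
        rows_i.append(np.array([id_pos[s] for s in ids]))
    return np.vstack(rows_X), np.concatenate(rows_t), np.concatenate(rows_i)


def _error_moments(resid: np.ndarray, t_idx: np.ndarray, pairing) -> tuple[float, float, float]:
    k1p, k2p, _, _ = pairing
    v1 = float(np.var(resid[t_idx == 0], ddof=1)) if (t_idx == 0).sum() > 1 else 1.0
    v2 = float(np.var(resid[t_idx == 1], ddof=1)) if (t_idx == 1).sum() > 1 else 1.0
    if len(k1p) > 2:
        c = float(np.corrcoef(resid[k1p], resid[k2p])[0, 1])
        c = float(np.clip(c, -0.999, 0.999))
    else:
        c = 0.0
    return max(v1, 1e-300), max(v2, 1e-300), c


def _pairing(t_idx: np.ndarray, i_idx: np.ndarray):
    """Row-index bookkeeping: paired (t1,t2) rows and unpaired rows."""
    rows_t1 = {i: k for k, i in zip(np.flatnonzero(t_idx == 0), i_idx[t_idx == 0])}
    k1p, k2p, u2 = [], [], []
    for k in np.flatnonzero(t_idx == 1):
        k1 = rows_t1.get(i_idx[k])
        if k1 is None:
            u2.append(k)
        else:
            k1p.append(k1)
            k2p.append(k)
    paired_t1 = set(k1p)
    u1 = [k for k in np.flatnonzero(t_idx == 0) if k not in paired_t1]
    return (
        np.asarray(k1p, dtype=int),
        np.asarray(k2p, dtype=int),
        np.asarray(u1, dtype=int),
        np.asarray(u2, dtype=int),
    )


def _whiten(X: np.ndarray, y: np.ndarray, pairing, v1: float, v2: float, c: float):
    """Transform rows so errors become iid under the 2x2 block covariance
    (forward-solve against the block Cholesky factor)."""
    k1p, k2p, u1, u2 = pairing
    Xw = np.empty_like(X)
    yw = np.empty_like(y)
    s1, s2 = np.sqrt(v1), np.sqrt(v2)
    # Cholesky of [[v1, c*s1*s2], [c*s1*s2, v2]]
    l21 = c * s2
    l22 = s2 * np.sqrt(1.0 - c * c)
    if len(k1p):
        Xw[k1p] = X[k1p] / s1
        yw[k1p] = y[k1p] / s1
        Xw[k2p] = (X[k2p] - l21 * Xw[k1p]) / l22
        yw[k2p] = (y[k2p] - l21 * yw[k1p]) / l22
    if len(u1):
        Xw[u1] = X[u1] / s1
        yw[u1] = y[u1] / s1
    if len(u2):
        Xw[u2] = X[u2] / s2
        yw[u2] = y[u2] / s2
    return Xw, yw


def fit_gls_persistence(
    residuals: dict[str, pd.DataFrame],
    exposure: pd.Series,
    covariates: dict[str, pd.DataFrame] | None = None,
    covariate_columns: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Iterated-FGLS persistence model per CpG.

    Parameters
    ----------
    residuals
        ``{"t1": frame, "t2": frame}`` of residualized methylation
        (samples x CpGs); the CpG sets must match. Individuals may be
        missing from one timepoint.
    exposure
        Time-invariant exposure indicator indexed by sample id, covering
        every individual present at either timepoint.
    covariates, covariate_columns
        Optional study covariates per timepoint, added as linear terms.
    """
    covariate_columns = list(covariate_columns or [])
    if set(residuals) != {"t1", "t2"}:
        raise ValueError("residuals must be keyed 't1' and 't2'")
    r1, r2 = residuals["t1"], residuals["t2"]
    if list(r1.columns) != list(r2.columns):
        raise ValueError("CpG sets differ between timepoints")
    ids_t = {"t1": r1.index, "t2": r2.index}
    paired = ids_t["t1"].intersection(ids_t["t2"])
    if len(paired) < 2:
        raise ValueError("fewer than 2 individuals with both timepoints")
    X, t_idx, i_idx = _stack_design(exposure, covariates, covariate_columns, ids_t)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient persistence design")

    records = []
    n_ind = len(ids_t["t1"].union(ids_t["t2"]))
    pairing = _pairing(t_idx, i_idx)
    for cpg in r1.columns:
        y = np.concatenate([r1[cpg].to_numpy(float), r2[cpg].to_numpy(float)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        v1 = v2 = 1.0
        c = 0.0
        converged = False
        for _ in range(max_iter):
            resid = y - X @ beta
            v1, v2, c = _error_moments(resid, t_idx, pairing)
            Xw, yw = _whiten(X, y, pairing, v1, v2, c)
            beta_new, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
            delta = np.max(np.abs(beta_new - beta) / np.maximum(np.abs(beta), 1e-12))
            beta = beta_new
            if delta < tol:
                converged = True
                break
        if not converged:
            logger.warning("persistence FGLS did not converge for %s", cpg)
        Xw, yw = _whiten(X, y, pairing, v1, v2, c)
        cov_beta = np.linalg.inv(Xw.T @ Xw)
        b1 = float(beta[1])
        b_int = float(beta[3])
        se1 = float(np.sqrt(cov_beta[1, 1]))
        se_int = float(np.sqrt(cov_beta[3, 3]))
        b2 = b1 + b_int
        se2 = float(np.sqrt(cov_beta[1, 1] + cov_beta[3, 3] + 2.0 * cov_beta[1, 3]))
        records.append(
            PersistenceRecord(
                cpg_id=cpg,
                beta_t1=b1,
                se_t1=se1,
                beta_t2=b2,
                se_t2=se2,
                interaction_beta=b_int,
                interaction_se=se_int,
                equality_pval=float(2.0 * stats.norm.sf(abs(b_int / se_int))),
                resid_var_t1=v1,
                resid_var_t2=v2,
                resid_corr=c,
                n_individuals=n_ind,
                n_paired=len(paired),
                converged=converged,
            )
        )
    return pd.DataFrame([r.__dict__ for r in records])
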