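"""Inverse-variance weighted fixed-effects meta-analysis and region pruning.

Per-CpG estimates from several cohorts are pooled with weights
``w_i = 1/se_i^2`` (so the pooled standard error is ``(sum w_i)^(-1/2)``),
significance is thresholded at a strict ``P < alpha`` (default 1e-7, the
conventional 450k-array epigenome-wide level), and significant CpGs are
partitioned into genomic regions by greedily selecting the CpG with the
strongest association as a region leader and absorbing all CpGs within
half a window (default ±500 kb of a 1-Mb window) on the same chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ivw_meta",
    "apply_threshold",
    "select_leading_cpgs",
    "RegionAssignment",
    "regions_to_frame",
    "bh_fdr",
]

GENOME_WIDE_ALPHA = 1e-7
DEFAULT_WINDOW_BP = 1_000_000


def ivw_meta(per_study_records: dict[str, pd.DataFrame] | list[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effects IVW meta-analysis of per-cohort EWAS tables.

    Each table needs columns ``cpg_id, beta, se``. CpGs present in only a
    subset of studies are pooled over that subset, with ``k_studies``
    recording the count and ``direction`` holding one '+'/'-' character
    per contributing study ('?' where a study lacks the CpG). Cochran's Q
    is computed and reported per CpG but never gates inclusion.
    """
    if isinstance(per_study_records, list):
        per_study_records = {f"study{i + 1}": t for i, t in enumerate(per_study_records)}
    studies = list(per_study_records)
    frames = []
    for name in studies:
        t = per_study_records[name]
        if (t["se"] <= 0).any():
            bad = t.loc[t["se"] <= 0, "cpg_id"].tolist()
            raise ValueError(f"study {name!r} has non-positive se for CpGs {bad[:5]}")
        frames.append(t.set_index("cpg_id")[["beta", "se"]].rename(columns=lambda c: f"{c}_{name}"))
    wide = pd.concat(frames, axis=1, join="outer")

    betas = wide[[f"beta_{s}" for s in studies]].to_numpy(float)
    ses = wide[[f"se_{s}" for s in studies]].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 1.0 / ses**2
    present = np.isfinite(betas) & np.isfinite(w)
    w = np.where(present, w, 0.0)
    bw = np.where(present, betas * w, 0.0)
    sw = w.sum(axis=1)
    beta = bw.sum(axis=1) / sw
    se = sw**-0.5
    z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    q = np.where(present, w * (betas - beta[:, None]) ** 2, 0.0).sum(axis=1)
    k = present.sum(axis=1)
    q_pval = np.where(k > 1, stats.chi2.sf(q, np.maximum(k - 1, 1)), np.nan)
    direction = [
        "".join("?" if not p else ("+" if b >= 0 else "-") for b, p in zip(brow, prow))
        for brow, prow in zip(betas, present)
    ]
    out = pd.DataFrame(
        {
            "cpg_id": wide.index,
            "beta": beta,
            "se": se,
            "z": z,
            "pval": pval,
            "k_studies": k,
            "direction": direction,
            "cochran_q": q,
            "cochran_q_pval": q_pval,
        }
    ).reset_index(drop=True)
    logger.info("ivw_meta: %d CpGs over %d studies", len(out), len(studies))
    return out


def apply_threshold(meta: pd.DataFrame, alpha: float = GENOME_WIDE_ALPHA) -> pd.DataFrame:
    """Keep records with ``pval`` strictly below ``alpha``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
    return meta.loc[meta["pval"] < alpha].reset_index(drop=True)


@dataclass
class RegionAssignment:
    """One genomic region: a leading CpG and the members it absorbed."""

    region_id: str
    chromosome: str
    leading_cpg: str
    member_cpgs: list[str] = field(default_factory=list)
    window_halfwidth: int = DEFAULT_WINDOW_BP // 2


def _chrom_sort_key(label: str) -> tuple[int, int, str]:
    s = str(label)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


def select_leading_cpgs(significant: pd.DataFrame, window: int = DEFAULT_WINDOW_BP) -> list[RegionAssignment]:
    """Greedy leading-CpG region pruning.

    ``significant`` needs columns ``cpg_id, pval, chrom, pos`` (annotation
    already joined). Repeatedly the unassigned CpG with the smallest P is
    taken as a region leader and all unassigned CpGs on its chromosome
    within ``window/2`` of its position are absorbed. Ties in P (which
    occur in rounded published tables) are broken by descending |beta/se|
    when those columns are present — a finer proxy for association
    strength than a rounded P — then by (chromosome, position) so the
    partition is deterministic and independent of input order.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window!r}")
    required = {"cpg_id", "pval", "chrom", "pos"}
    missing_cols = required - set(significant.columns)
    if missing_cols:
        raise ValueError(f"annotation columns missing: {sorted(missing_cols)}")
    bad = significant.loc[significant[["chrom", "pos"]].isna().any(axis=1), "cpg_id"]
    if len(bad):
        raise ValueError(f"missing annotation for significant CpGs: {bad.tolist()}")

    df = significant.copy().reset_index(drop=True)
    df["_absz"] = (
        (df["beta"] / df["se"]).abs() if {"beta", "se"} <= set(df.columns) else 0.0
    )
    df["_ckey"] = df["chrom"].map(_chrom_sort_key)
    order = df.sort_values(
        ["pval", "_absz", "_ckey", "pos"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).index

    half = window // 2
    unassigned = np.ones(len(df), dtype=bool)
    chrom = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy(np.int64)
    regions: list[RegionAssignment] = []
    for i in order:
        if not unassigned[i]:
            continue
        members = unassigned & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= half)
        idx = np.flatnonzero(members)
        # deterministic member order: by position
        idx = idx[np.argsort(pos[idx], kind="mergesort")]
        regions.append(
            RegionAssignment(
                region_id=f"region_{len(regions) + 1:03d}",
                chromosome=chrom[i],
                leading_cpg=df.at[i, "cpg_id"],
                member_cpgs=[df.at[j, "cpg_id"] for j in idx],
                window_halfwidth=half,
            )
        )
        unassigned[members] = False
    return regions


def regions_to_frame(regions: list[RegionAssignment]) -> pd.DataFrame:
    """Tabular form of a region assignment (members semicolon-joined)."""
    return pd.DataFrame(
        {
            "region_id": [r.region_id for r in regions],
            "chromosome": [r.chromosome for r in regions],
            "leading_cpg": [r.leading_cpg for r in regions],
            "member_count": [len(r.member_cpgs) for r in regions],
            "members": [";".join(r.member_cpgs) for r in regions],
        }
    )


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted P values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
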