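"""Two-sample Mendelian randomization from summary statistics.

CpG methylation is the exposure, instrumented by mQTL SNPs; disease GWAS
summary statistics supply the SNP→outcome effects. The stages are:

* :func:`select_and_clump` — instrument selection at an mQTL P threshold
  (default 1e-7) followed by greedy LD clumping (1-Mb window, r² < 0.001).
* :func:`harmonize` — align exposure and outcome records to the same
  effect allele, excluding strand-ambiguous palindromic SNPs.
* :func:`wald_ratio` / :func:`ivw_mr` — causal-effect estimation with a
  single instrument (ratio estimate) or several (fixed-effects
  inverse-variance weighting, equivalent to a zero-intercept weighted
  regression of outcome betas on exposure betas).
* :func:`mr_scan` — all CpG × trait pairs with global Benjamini–Hochberg
  correction across the scan.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .meta import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "InstrumentSet",
    "MRRecord",
    "select_and_clump",
    "harmonize",
    "wald_ratio",
    "ivw_mr",
    "mr_scan",
    "consistency_filter",
]

INSTRUMENT_P_THRESHOLD = 1e-7
CLUMP_WINDOW_BP = 1_000_000
CLUMP_R2 = 0.001

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: palindromic SNPs with minor-allele frequency this close to 0.5 cannot be
#: strand-resolved from frequency and are excluded
PALINDROMIC_EAF_BAND = (0.42, 0.58)


@dataclass
class InstrumentSet:
    """Retained instruments for one CpG, with an exclusion log."""

    cpg_id: str
    snps: pd.DataFrame  # mQTL rows of retained instruments
    exclusions: list[tuple[str, str]] = field(default_factory=list)  # (snp, reason)


@dataclass
class MRRecord:
    cpg_id: str
    trait_id: str
    method: str  # wald_ratio | ivw
    beta: float
    se: float
    pval: float
    n_snps: int
    fdr_pval: float | None = None


def select_and_clump(
    mqtl: pd.DataFrame,
    ld: pd.DataFrame,
    p_threshold: float = INSTRUMENT_P_THRESHOLD,
    window_bp: int = CLUMP_WINDOW_BP,
    r2_threshold: float = CLUMP_R2,
) -> dict[str, InstrumentSet]:
    """Instrument selection and greedy LD clumping per CpG.

    ``mqtl`` needs columns ``snp, cpg, beta, se, pval`` (and optionally
    ``chrom, pos`` for the distance criterion); ``ld`` is a square
    correlation matrix (r, not r²) indexed by SNP id. Candidates below the
    P threshold are visited in ascending P; each retained SNP removes the
    remaining candidates that are within ``window_bp/2`` of it (same
    chromosome) *and* have r² ≥ ``r2_threshold`` with it.
    """
    out: dict[str, InstrumentSet] = {}
    have_pos = {"chrom", "pos"} <= set(mqtl.columns)
    for cpg, grp in mqtl.groupby("cpg", sort=True):
        exclusions: list[tuple[str, str]] = []
        cand = grp.loc[grp["pval"] < p_threshold]
        for snp in grp.loc[grp["pval"] >= p_threshold, "snp"]:
            exclusions.append((snp, "pval"))
        missing = [s for s in cand["snp"] if s not in ld.index]
        if missing:
            raise ValueError(f"SNPs absent from LD matrix: {missing}")
        cand = cand.sort_values(["pval", "snp"], kind="mergesort")
        retained_rows = []
        dropped: set[str] = set()
        for _, row in cand.iterrows():
            if row["snp"] in dropped:
                continue
            retained_rows.append(row)
            for _, other in cand.iterrows():
                s = other["snp"]
                if s == row["snp"] or s in dropped or any(r["snp"] == s for r in retained_rows):
                    continue
                within = True
                if have_pos:
                    within = (str(other["chrom"]) == str(row["chrom"])) and (
                        abs(int(other["pos"]) - int(row["pos"])) <= window_bp // 2
                    )
                r2 = float(ld.loc[row["snp"], s]) ** 2
                if within and r2 >= r2_threshold:
                    dropped.add(s)
                    exclusions.append((s, "ld"))
        retained = (
            pd.DataFrame(retained_rows).reset_index(drop=True)
            if retained_rows
            else grp.iloc[0:0].reset_index(drop=True)
        )
        out[cpg] = InstrumentSet(cpg_id=cpg, snps=retained, exclusions=exclusions)
    return out


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def harmonize(exposure: pd.Series, outcome: pd.Series) -> tuple[pd.Series | None, str | None]:
    """Align an outcome record to the exposure record's effect allele.

    Returns ``(harmonized outcome, None)`` or ``(None, reason)`` when the
    SNP must be excluded (``palindromic-ambiguous`` or
    ``allele-mismatch``). The harmonized record has the outcome beta sign
    flipped and eaf complemented when the outcome's alleles were coded the
    other way around (directly or on the opposite strand).
    """
    if exposure["snp"] != outcome["snp"]:
        raise ValueError("harmonize called on different SNPs")
    e_ea, e_oa = str(exposure["effect_allele"]), str(exposure["other_allele"])
    o_ea, o_oa = str(outcome["effect_allele"]), str(outcome["other_allele"])

    if _is_palindromic(e_ea, e_oa):
        eaf = float(exposure.get("eaf", np.nan))
        lo, hi = PALINDROMIC_EAF_BAND
        if not np.isfinite(eaf) or lo <= eaf <= hi:
            return None, "palindromic-ambiguous"
        # orientation resolved by frequency: effect alleles agree when the
        # two eafs sit on the same side of 0.5
        o_eaf = float(outcome.get("eaf", np.nan))
        if not np.isfinite(o_eaf):
            return None, "palindromic-ambiguous"
        # for palindromic SNPs allele labels cannot resolve strand; the
        # frequencies decide: same side of 0.5 -> same effect allele
        same_side = (eaf - 0.5) * (o_eaf - 0.5) > 0
        h = outcome.copy()
        if not same_side:
            h["beta"] = -h["beta"]
            h["eaf"] = 1.0 - h["eaf"]
        h["effect_allele"], h["other_allele"] = e_ea, e_oa
        return h, None

    if (o_ea, o_oa) == (e_ea, e_oa):
        return outcome.copy(), None
    if (o_ea, o_oa) == (e_oa, e_ea):
        h = outcome.copy()
        h["beta"] = -h["beta"]
        h["eaf"] = 1.0 - h["eaf"]
        h["effect_allele"], h["other_allele"] = e_ea, e_oa
        return h, None
    oc_ea, oc_oa = _COMPLEMENT.get(o_ea, "?"), _COMPLEMENT.get(o_oa, "?")
    if (oc_ea, oc_oa) == (e_ea, e_oa):
        h = outcome.copy()
        h["effect_allele"], h["other_allele"] = e_ea, e_oa
        return h, None
    if (oc_ea, oc_oa) == (e_oa, e_ea):
        h = outcome.copy()
        h["beta"] = -h["beta"]
        h["eaf"] = 1.0 - h["eaf"]
        h["effect_allele"], h["other_allele"] = e_ea, e_oa
        return h, None
    return None, "allele-mismatch"


def wald_ratio(
    bGE: float,
    seGE: float,
    bGD: float,
    seGD: float,
    se_method: str = "first-order",
    cpg_id: str = "",
    trait_id: str = "",
) -> MRRecord:
    """Single-instrument causal estimate bGD / bGE.

    ``se_method='first-order'`` ignores instrument uncertainty
    (``seGD/|bGE|``); ``'delta'`` adds the second-order term
    ``sqrt(seGD²/bGE² + bGD²·seGE²/bGE⁴)``.
    """
    if bGE == 0:
        raise ValueError("SNP→exposure effect is zero: Wald ratio undefined (weak instrument)")
    beta = bGD / bGE
    if se_method == "first-order":
        se = seGD / abs(bGE)
    elif se_method == "delta":
        se = math.sqrt(seGD**2 / bGE**2 + bGD**2 * seGE**2 / bGE**4)
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    pval = 2.0 * stats.norm.sf(abs(beta / se))
    return MRRecord(cpg_id=cpg_id, trait_id=trait_id, method="wald_ratio", beta=beta, se=se, pval=pval, n_snps=1)


def ivw_mr(harmonized: pd.DataFrame, cpg_id: str = "", trait_id: str = "") -> MRRecord:
    """Fixed-effects IVW over ≥ 2 instruments.

    ``harmonized`` needs columns ``beta_exposure, beta_outcome,
    se_outcome``. beta = Σ(bGE·bGD/seGD²) / Σ(bGE²/seGD²);
    se = (Σ bGE²/seGD²)^(-1/2).
    """
    if len(harmonized) < 2:
        raise ValueError("IVW requires >= 2 instruments; use wald_ratio")
    bge = harmonized["beta_exposure"].to_numpy(float)
    bgd = harmonized["beta_outcome"].to_numpy(float)
    segd = harmonized["se_outcome"].to_numpy(float)
    w = bge**2 / segd**2
    beta = float((bge * bgd / segd**2).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    pval = 2.0 * stats.norm.sf(abs(beta / se))
    return MRRecord(cpg_id=cpg_id, trait_id=trait_id, method="ivw", beta=beta, se=se, pval=pval, n_snps=len(harmonized))


def consistency_filter(
    instruments: dict[str, InstrumentSet], mqtl_by_timepoint: list[pd.DataFrame]
) -> dict[str, InstrumentSet]:
    """Drop instruments whose mQTL effect changes sign across timepoints.

    Generalizes the exclusion of SNP–CpG pairs whose association is not
    consistent across the life-course mQTL tables supplied.
    """
    out = {}
    for cpg, iset in instruments.items():
        keep_rows = []
        excl = list(iset.exclusions)
        for _, row in iset.snps.iterrows():
            signs = []
            for tab in mqtl_by_timepoint:
                hit = tab.loc[(tab["snp"] == row["snp"]) & (tab["cpg"] == cpg), "beta"]
                if len(hit):
                    signs.append(math.copysign(1.0, float(hit.iloc[0])))
            if signs and (max(signs) != min(signs) or math.copysign(1.0, row["beta"]) != signs[0]):
                excl.append((row["snp"], "timepoint-inconsistent"))
            else:
                keep_rows.append(row)
        out[cpg] = InstrumentSet(
            cpg_id=cpg,
            snps=pd.DataFrame(keep_rows).reset_index(drop=True) if keep_rows else iset.snps.iloc[0:0],
            exclusions=excl,
        )
    return out


def mr_scan(
    instruments: dict[str, InstrumentSet],
    gwas: pd.DataFrame,
    se_method: str = "first-order",
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Causal estimates for every estimable CpG × trait pair, with global
    Benjamini–Hochberg adjustment across the scan.

    ``gwas`` needs columns ``snp, effect_allele, other_allele, eaf, beta,
    se, trait_id``. Traits with no harmonizable instrument for a CpG are
    skipped and logged.
    """
    records: list[MRRecord] = []
    for trait_id, gtab in gwas.groupby("trait_id", sort=True):
        gtab = gtab.set_index("snp", drop=False)
        for cpg, iset in sorted(instruments.items()):
            rows = []
            for _, erow in iset.snps.iterrows():
                if erow["snp"] not in gtab.index:
                    logger.info("%s/%s: SNP %s absent from GWAS", cpg, trait_id, erow["snp"])
                    continue
                h, reason = harmonize(erow, gtab.loc[erow["snp"]])
                if h is None:
                    logger.info("%s/%s: %s excluded (%s)", cpg, trait_id, erow["snp"], reason)
                    continue
                rows.append(
                    {
                        "snp": erow["snp"],
                        "beta_exposure": float(erow["beta"]),
                        "se_exposure": float(erow["se"]),
                        "beta_outcome": float(h["beta"]),
                        "se_outcome": float(h["se"]),
                    }
                )
            if not rows:
                logger.info("%s/%s: no overlapping instruments; skipped", cpg, trait_id)
                continue
            hdf = pd.DataFrame(rows)
            if len(hdf) == 1:
                r = hdf.iloc[0]
                rec = wald_ratio(
                    r["beta_exposure"], r["se_exposure"], r["beta_outcome"], r["se_outcome"],
                    se_method=se_method, cpg_id=cpg, trait_id=trait_id,
                )
            else:
                rec = ivw_mr(hdf, cpg_id=cpg, trait_id=trait_id)
            records.append(rec)
    if not records:
        return pd.DataFrame(
            columns=["cpg_id", "trait_id", "method", "beta", "se", "pval", "n_snps", "fdr_pval", "significant"]
        )
    out = pd.DataFrame([r.__dict__ for r in records])
    out["fdr_pval"] = bh_fdr(out["pval"].to_numpy())
    out["significant"] = out["fdr_pval"] < fdr_alpha
    return out
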