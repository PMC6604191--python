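"""Synthetic cohort, genotype, and summary-statistic generator.

Every downstream stage of the pipeline (per-cohort EWAS, meta-analysis,
persistence, Mendelian randomization, mediation) is exercised on data from
this module. The generator plants known effects — exposure shifts in
methylation with dose dependence, a purely shared-environment paternal
path, partial persistence at a second timepoint, SNP instruments for CpGs,
and outcomes with a known mediated fraction — and returns a
:class:`TruthRecord` so that recovery can be tested against ground truth.

The generative model for methylation at CpG j in individual i is

    beta_ij = mu_j + effect_j * smoke_i + slope_j * cigs_i
              + covariate loadings + cell-type mixture + eps_ij

with ``eps_ij ~ N(0, noise_sd)``, clipped to [0, 1]. Maternal smoking is a
Bernoulli exposure; cigarettes/day for exposed mothers follow a
zero-truncated Poisson ("at least one cigarette per day"). Paternal
smoking is generated from a latent environment shared with maternal
smoking and has *no* direct effect on methylation — the negative-control
assumption.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "CohortBundle",
    "TruthRecord",
    "simulate_cohort",
    "simulate_second_timepoint",
    "simulate_mr_inputs",
]

#: Dirichlet base weights for white-blood-cell proportions (granulocytes
#: dominate whole blood); truncated/renormalized to ``cell_type_count``.
_CELL_ALPHA = np.array([55.0, 25.0, 8.0, 5.0, 4.0, 3.0, 2.0, 2.0])


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults emulate a single birth-cohort study: ~18% prevalence of
    sustained maternal smoking, around three cigarettes/day among exposed
    mothers, moderate assortment between parental smoking, and planted
    effect sizes on the 0.005–0.08 beta-value scale typical of
    smoking-associated CpGs.
    """

    n_samples: int = 1000
    n_cpgs: int = 50
    n_chromosomes: int = 22
    exposure_prevalence: float = 0.18
    mean_cigs_per_day_given_exposed: float = 3.0
    paternal_shared_env_corr: float = 0.4
    paternal_prevalence: float = 0.35
    own_smoking_prevalence: float = 0.54
    effect_sizes: dict[int, float] = field(default_factory=dict)
    dose_slopes: dict[int, float] = field(default_factory=dict)
    persistence_fractions: dict[int, float] = field(default_factory=dict)
    noise_sd: float = 0.02
    cell_type_count: int = 6
    n_genetic_pcs: int = 4
    n_technical_pcs: int = 10
    n_snps: int = 0
    n_traits: int = 1
    mqtl_effects: dict[tuple[int, int], float] = field(default_factory=dict)
    causal_cpg_effects_on_outcome: dict[int, float] = field(default_factory=dict)
    direct_exposure_effect_on_outcome: float = 0.0
    outcome_noise_sd: float = 1.0
    binary_outcome_prevalence: float = 0.10
    #: residual correlation of a sample's noise across the two timepoints
    timepoint_residual_corr: float = 0.5
    #: multiplier on noise_sd at the second timepoint (heteroskedastic errors)
    t2_noise_scale: float = 1.2
    #: pairwise LD (r) among SNPs instrumenting the same CpG
    ld_r: float = 0.0
    #: sample sizes behind the simulated mQTL and GWAS summary statistics
    mqtl_sample_size: int = 1000
    gwas_sample_size: int = 50000
    #: when False, summary betas are emitted without sampling error
    #: (standard errors still reflect the sample sizes)
    summary_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_samples", "n_cpgs", "n_chromosomes"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        for name in ("exposure_prevalence", "paternal_prevalence", "own_smoking_prevalence"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v!r}")
        if not (np.isfinite(self.mean_cigs_per_day_given_exposed) and self.mean_cigs_per_day_given_exposed > 0):
            raise ValueError(
                "mean_cigs_per_day_given_exposed must be a positive real, "
                f"got {self.mean_cigs_per_day_given_exposed!r}"
            )
        if not (np.isfinite(self.paternal_shared_env_corr) and -1.0 <= self.paternal_shared_env_corr <= 1.0):
            raise ValueError(
                f"paternal_shared_env_corr must lie in [-1, 1], got {self.paternal_shared_env_corr!r}"
            )
        if not (np.isfinite(self.noise_sd) and self.noise_sd >= 0.0):
            raise ValueError(f"noise_sd must be a nonnegative real, got {self.noise_sd!r}")
        if not (np.isfinite(self.timepoint_residual_corr) and -1.0 <= self.timepoint_residual_corr <= 1.0):
            raise ValueError(
                f"timepoint_residual_corr must lie in [-1, 1], got {self.timepoint_residual_corr!r}"
            )
        if not (np.isfinite(self.ld_r) and -1.0 < self.ld_r < 1.0):
            raise ValueError(f"ld_r must lie in (-1, 1), got {self.ld_r!r}")
        for mapping, name in (
            (self.effect_sizes, "effect_sizes"),
            (self.dose_slopes, "dose_slopes"),
            (self.persistence_fractions, "persistence_fractions"),
            (self.causal_cpg_effects_on_outcome, "causal_cpg_effects_on_outcome"),
        ):
            for k, v in mapping.items():
                if not (0 <= int(k) < self.n_cpgs):
                    raise ValueError(f"{name}: CpG index {k} outside [0, n_cpgs)")
                if not np.isfinite(v):
                    raise ValueError(f"{name}: non-finite value for CpG {k}")
        for f_, v in self.persistence_fractions.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"persistence_fractions: value for CpG {f_} outside [0, 1]")
        for (snp, cpg), v in self.mqtl_effects.items():
            if not (0 <= int(snp) < max(self.n_snps, 1)):
                raise ValueError(f"mqtl_effects: SNP index {snp} outside [0, n_snps)")
            if not (0 <= int(cpg) < self.n_cpgs):
                raise ValueError(f"mqtl_effects: CpG index {cpg} outside [0, n_cpgs)")
            if not np.isfinite(v):
                raise ValueError(f"mqtl_effects: non-finite value for SNP {snp}, CpG {cpg}")


@dataclass
class CohortBundle:
    """One cohort: methylation matrix, CpG annotation, sample covariates."""

    methylation: pd.DataFrame  # samples x CpGs, beta values in [0, 1]
    annotation: pd.DataFrame  # cpg_id, chrom, pos, gene
    covariates: pd.DataFrame  # indexed by sample_id
    timepoint: str = "t1"

    def __post_init__(self) -> None:
        if not self.methylation.index.equals(self.covariates.index):
            raise ValueError("sample sets of methylation and covariates differ")
        if self.methylation.index.has_duplicates:
            raise ValueError("duplicated sample ids")
        if self.annotation["cpg_id"].duplicated().any():
            raise ValueError("duplicated CpG ids in annotation")
        cell_cols = self.cell_columns
        if cell_cols:
            total = self.covariates[cell_cols].to_numpy().sum(axis=1)
            if (self.covariates[cell_cols].to_numpy() < -1e-12).any():
                raise ValueError("negative cell proportions")
            if np.abs(total - 1.0).max() > 1e-8:
                raise ValueError("cell proportions do not sum to 1")
        if (self.annotation["pos"] <= 0).any():
            raise ValueError("positions must be strictly positive")

    @property
    def sample_ids(self) -> pd.Index:
        return self.methylation.index

    @property
    def cpg_ids(self) -> pd.Index:
        return self.methylation.columns

    @property
    def cell_columns(self) -> list[str]:
        return [c for c in self.covariates.columns if c.startswith("cell_")]

    def subset(self, sample_ids) -> "CohortBundle":
        return CohortBundle(
            methylation=self.methylation.loc[sample_ids],
            annotation=self.annotation,
            covariates=self.covariates.loc[sample_ids],
            timepoint=self.timepoint,
        )


@dataclass
class TruthRecord:
    """Realized ground truth for parameter-recovery tests."""

    effect_sizes: dict[str, float] = field(default_factory=dict)
    dose_slopes: dict[str, float] = field(default_factory=dict)
    persistence_fractions: dict[str, float] = field(default_factory=dict)
    mr_causal_effects: dict[str, float] = field(default_factory=dict)
    acme: float | None = None
    ade: float | None = None
    total_effect: float | None = None
    prop_mediated: float | None = None

    def __post_init__(self) -> None:
        if self.total_effect not in (None, 0.0) and self.acme is not None:
            implied = self.acme / self.total_effect
            if self.prop_mediated is not None and not math.isclose(
                implied, self.prop_mediated, rel_tol=1e-9, abs_tol=1e-12
            ):
                raise ValueError("prop_mediated inconsistent with acme/total_effect")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _cpg_name(j: int) -> str:
    return f"cpg{j:05d}"


def _snp_name(s: int) -> str:
    return f"rs{s + 1:06d}"


def _zt_poisson_lambda(mean: float) -> float:
    """Rate of a zero-truncated Poisson with the given mean (> 1)."""
    if mean <= 1.0:
        raise ValueError("zero-truncated Poisson mean must exceed 1")
    f = lambda lam: lam / (1.0 - math.exp(-lam)) - mean
    return optimize.brentq(f, 1e-9, mean * 2 + 10)


def _zt_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson by inverse CDF on the shifted uniform."""
    u = rng.uniform(size=size)
    p0 = math.exp(-lam)
    return stats.poisson.ppf(p0 + u * (1.0 - p0), lam).astype(int)


def _structural_params(config: SimulationConfig) -> dict:
    """CpG-level parameters shared by both timepoints (seed-derived)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    m = config.n_cpgs
    k = config.cell_type_count
    params = {
        "mu": rng.uniform(0.15, 0.85, size=m),
        "chrom": rng.integers(1, config.n_chromosomes + 1, size=m),
        "pos": rng.integers(1, 2**27, size=m),
        "sex_load": rng.normal(0.0, 0.002, size=m),
        "bmi_load": rng.normal(0.0, 0.002, size=m),
        "age_load": rng.normal(0.0, 0.002, size=m),
        "cell_load": rng.normal(0.0, 0.02, size=(k, m)) if k > 0 else np.zeros((0, m)),
    }
    return params


def _annotation_frame(config: SimulationConfig, params: dict) -> pd.DataFrame:
    m = config.n_cpgs
    return pd.DataFrame(
        {
            "cpg_id": [_cpg_name(j) for j in range(m)],
            "chrom": [str(c) for c in params["chrom"]],
            "pos": params["pos"].astype(int),
            "gene": [f"GENE{j % max(m // 2, 1)}" for j in range(m)],
        }
    )


def _draw_covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_samples
    # Shared household environment drives both parents' smoking: a bivariate
    # normal latent pair thresholded at each parent's prevalence gives binary
    # indicators whose latent (tetrachoric) correlation is the configured one.
    rho = config.paternal_shared_env_corr
    cov = np.array([[1.0, rho], [rho, 1.0]])
    latent = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    maternal = (latent[:, 0] < stats.norm.ppf(config.exposure_prevalence)).astype(int)
    paternal = (latent[:, 1] < stats.norm.ppf(config.paternal_prevalence)).astype(int)

    cigs = np.zeros(n)
    n_exp = int(maternal.sum())
    if n_exp and config.mean_cigs_per_day_given_exposed > 1.0:
        lam = _zt_poisson_lambda(config.mean_cigs_per_day_given_exposed)
        cigs[maternal == 1] = _zt_poisson(rng, lam, n_exp)
    elif n_exp:
        cigs[maternal == 1] = 1.0  # degenerate mean: everyone at the minimum

    cov_df = pd.DataFrame(index=pd.Index([f"S{i:05d}" for i in range(n)], name="sample_id"))
    cov_df["maternal_smoking"] = maternal
    cov_df["cigs_per_day"] = cigs
    cov_df["paternal_smoking"] = paternal
    cov_df["own_smoking"] = rng.binomial(1, config.own_smoking_prevalence, size=n)
    cov_df["sex"] = rng.binomial(1, 0.5, size=n)
    cov_df["bmi"] = rng.normal(25.0, 4.0, size=n)
    cov_df["social_class"] = rng.integers(1, 6, size=n)
    cov_df["age"] = rng.normal(30.0, 2.0, size=n)
    for p in range(config.n_genetic_pcs):
        cov_df[f"gpc{p + 1}"] = rng.normal(0.0, 1.0, size=n)
    return cov_df


def _draw_timepoint_covariates(
    config: SimulationConfig, rng: np.random.Generator, n: int
) -> pd.DataFrame:
    """Technical PCs and cell proportions, redrawn per timepoint."""
    out = {}
    for p in range(config.n_technical_pcs):
        out[f"tpc{p + 1}"] = rng.normal(0.0, 1.0, size=n)
    k = config.cell_type_count
    if k > 0:
        alpha = _CELL_ALPHA[:k] if k <= len(_CELL_ALPHA) else np.full(k, 5.0)
        props = rng.dirichlet(alpha, size=n)
        for c in range(k):
            out[f"cell_{c + 1}"] = props[:, c]
    return pd.DataFrame(out)


def _methylation_mean(
    config: SimulationConfig,
    params: dict,
    covariates: pd.DataFrame,
    effect_scale: np.ndarray,
) -> np.ndarray:
    """Noise-free methylation matrix; effect_scale in [0,1] per CpG scales
    the planted exposure and dose effects (1 at timepoint 1, the
    persistence fraction at timepoint 2)."""
    n, m = len(covariates), config.n_cpgs
    y = np.tile(params["mu"], (n, 1))
    exposure = covariates["maternal_smoking"].to_numpy(float)
    cigs = covariates["cigs_per_day"].to_numpy(float)
    eff = np.zeros(m)
    for j, v in config.effect_sizes.items():
        eff[int(j)] = v
    slo = np.zeros(m)
    for j, v in config.dose_slopes.items():
        slo[int(j)] = v
    y += np.outer(exposure, eff * effect_scale)
    y += np.outer(cigs, slo * effect_scale)
    y += np.outer(covariates["sex"].to_numpy(float), params["sex_load"])
    y += np.outer((covariates["bmi"].to_numpy(float) - 25.0) / 4.0, params["bmi_load"])
    y += np.outer(covariates["age"].to_numpy(float) - 30.0, params["age_load"])
    k = config.cell_type_count
    if k > 0:
        cell_cols = [f"cell_{c + 1}" for c in range(k)]
        props = covariates[cell_cols].to_numpy(float)
        # center on the Dirichlet mean so cell loadings do not shift mu
        alpha = _CELL_ALPHA[:k] if k <= len(_CELL_ALPHA) else np.full(k, 5.0)
        y += (props - alpha / alpha.sum()) @ params["cell_load"]
    return y


def _clip_logged(y: np.ndarray) -> np.ndarray:
    n_clip = int(((y < 0) | (y > 1)).sum())
    if n_clip:
        frac = n_clip / y.size
        logger.info("clipped %d of %d beta values (%.4f%%)", n_clip, y.size, 100 * frac)
        if frac > 0.001:
            logger.warning("clipping fraction %.3f%% exceeds 0.1%%", 100 * frac)
    return np.clip(y, 0.0, 1.0)


def _truth_from_config(config: SimulationConfig) -> TruthRecord:
    acme = ade = te = prop = None
    if config.causal_cpg_effects_on_outcome or config.direct_exposure_effect_on_outcome:
        # exposure -> mediator path includes the dose slope times the mean
        # dose among exposed mothers (dose is 0 when unexposed)
        acme = sum(
            (
                config.effect_sizes.get(j, 0.0)
                + config.dose_slopes.get(j, 0.0) * config.mean_cigs_per_day_given_exposed
            )
            * b
            for j, b in config.causal_cpg_effects_on_outcome.items()
        )
        ade = config.direct_exposure_effect_on_outcome
        te = acme + ade
        prop = acme / te if te != 0 else None
    return TruthRecord(
        effect_sizes={_cpg_name(j): v for j, v in config.effect_sizes.items()},
        dose_slopes={_cpg_name(j): v for j, v in config.dose_slopes.items()},
        persistence_fractions={_cpg_name(j): v for j, v in config.persistence_fractions.items()},
        mr_causal_effects={_cpg_name(j): v for j, v in config.causal_cpg_effects_on_outcome.items()},
        acme=acme,
        ade=ade,
        total_effect=te,
        prop_mediated=prop,
    )


def simulate_cohort(config: SimulationConfig, timepoint: str = "t1") -> tuple[CohortBundle, TruthRecord]:
    """Generate one cohort at the first timepoint, plus its ground truth.

    Deterministic given ``config.seed``: two calls with the same config
    return bit-identical bundles.
    """
    config.validate()
    params = _structural_params(config)
    rng_cov = np.random.default_rng(np.random.SeedSequence([config.seed, 201]))
    rng_tp = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    rng_noise = np.random.default_rng(np.random.SeedSequence([config.seed, 203]))
    rng_out = np.random.default_rng(np.random.SeedSequence([config.seed, 205]))

    covariates = _draw_covariates(config, rng_cov)
    tp_cov = _draw_timepoint_covariates(config, rng_tp, config.n_samples)
    tp_cov.index = covariates.index
    covariates = pd.concat([covariates, tp_cov], axis=1)

    mean = _methylation_mean(config, params, covariates, np.ones(config.n_cpgs))
    noise = rng_noise.normal(0.0, 1.0, size=mean.shape) * config.noise_sd
    y = _clip_logged(mean + noise)

    meth = pd.DataFrame(y, index=covariates.index, columns=[_cpg_name(j) for j in range(config.n_cpgs)])

    # Outcomes with the planted mediation path structure: exposure acts on
    # the outcome directly and through the causal CpGs' methylation.
    lin = config.direct_exposure_effect_on_outcome * covariates["maternal_smoking"].to_numpy(float)
    for j, b in config.causal_cpg_effects_on_outcome.items():
        lin = lin + b * y[:, int(j)]
    covariates["outcome_continuous"] = lin + rng_out.normal(0.0, config.outcome_noise_sd, size=len(lin))
    liability = lin + rng_out.normal(0.0, 1.0, size=len(lin))
    thresh = np.quantile(liability, 1.0 - config.binary_outcome_prevalence)
    covariates["outcome_binary"] = (liability > thresh).astype(int)

    bundle = CohortBundle(
        methylation=meth,
        annotation=_annotation_frame(config, params),
        covariates=covariates,
        timepoint=timepoint,
    )
    return bundle, _truth_from_config(config)


def simulate_second_timepoint(
    bundle: CohortBundle, config: SimulationConfig, timepoint: str = "t2"
) -> CohortBundle:
    """Re-measure the same individuals at a later timepoint.

    The planted exposure (and dose) effect at the second timepoint is the
    first-timepoint effect scaled by the CpG's persistence fraction
    (default 1: fully persistent). Technical covariates and cell
    proportions are redrawn; noise is correlated within individual across
    timepoints at ``config.timepoint_residual_corr`` and scaled by
    ``config.t2_noise_scale`` (heteroskedastic between timepoints).
    """
    config.validate()
    params = _structural_params(config)
    expected_ids = pd.Index([f"S{i:05d}" for i in range(config.n_samples)], name="sample_id")
    if not bundle.sample_ids.equals(expected_ids):
        raise ValueError("sample set of bundle does not match config (mismatched sample sets)")

    rng_tp = np.random.default_rng(np.random.SeedSequence([config.seed, 302]))
    rng_noise1 = np.random.default_rng(np.random.SeedSequence([config.seed, 203]))
    rng_noise2 = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))

    keep = [
        "maternal_smoking", "cigs_per_day", "paternal_smoking", "own_smoking",
        "sex", "bmi", "social_class", "age",
        "outcome_continuous", "outcome_binary",
    ] + [c for c in bundle.covariates.columns if c.startswith("gpc")]
    covariates = bundle.covariates[[c for c in keep if c in bundle.covariates.columns]].copy()
    covariates["age"] = covariates["age"] + 16.0  # early adulthood -> midlife
    tp_cov = _draw_timepoint_covariates(config, rng_tp, config.n_samples)
    tp_cov.index = covariates.index
    covariates = pd.concat([covariates, tp_cov], axis=1)

    scale = np.ones(config.n_cpgs)
    for j, f in config.persistence_fractions.items():
        scale[int(j)] = f
    mean = _methylation_mean(config, params, covariates, scale)

    # replay the t1 noise stream so the within-individual correlation is real
    z1 = rng_noise1.normal(0.0, 1.0, size=mean.shape)
    z2 = rng_noise2.normal(0.0, 1.0, size=mean.shape)
    rho = config.timepoint_residual_corr
    eps = (rho * z1 + math.sqrt(1.0 - rho**2) * z2) * config.noise_sd * config.t2_noise_scale
    y = _clip_logged(mean + eps)

    meth = pd.DataFrame(y, index=covariates.index, columns=bundle.methylation.columns)
    return CohortBundle(
        methylation=meth,
        annotation=bundle.annotation,
        covariates=covariates,
        timepoint=timepoint,
    )


def _random_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    bases = np.array(list("ACGT"))
    ea = bases[rng.integers(0, 4, size=n)]
    shift = rng.integers(1, 4, size=n)
    oa = bases[(np.searchsorted(bases, ea) + shift) % 4]
    return ea, oa


def simulate_mr_inputs(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Two-sample MR inputs: mQTL table, GWAS table, LD matrix, truth.

    SNP→CpG effects come from ``config.mqtl_effects`` plus sampling error
    for ``mqtl_sample_size``; SNP→outcome effects are (true causal effect
    of the CpG) × (true SNP→CpG effect) plus sampling error — i.e. all
    instruments are valid, with no direct SNP→outcome path. Traits beyond
    those with planted effects are pure nulls.
    """
    config.validate()
    if config.n_snps < 1:
        raise ValueError("n_snps must be >= 1 for MR input simulation")
    for (snp, cpg), v in config.mqtl_effects.items():
        if v == 0.0 and int(cpg) in config.causal_cpg_effects_on_outcome:
            raise ValueError(
                f"mqtl effect for SNP {_snp_name(snp)} on designated instrument CpG "
                f"{_cpg_name(cpg)} is zero (unusable instrument)"
            )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 401]))
    n_snps = config.n_snps
    ea, oa = _random_alleles(rng, n_snps)
    eaf = rng.uniform(0.1, 0.9, size=n_snps)
    snp_chrom = rng.integers(1, config.n_chromosomes + 1, size=n_snps)
    snp_pos = rng.integers(1, 2**27, size=n_snps)

    # LD: exchangeable correlation ld_r within the SNP set of each CpG
    ld = np.eye(n_snps)
    by_cpg: dict[int, list[int]] = {}
    for (snp, cpg) in config.mqtl_effects:
        by_cpg.setdefault(int(cpg), []).append(int(snp))
    for snps in by_cpg.values():
        for a in snps:
            for b in snps:
                if a != b:
                    ld[a, b] = config.ld_r
    snp_ids = [_snp_name(s) for s in range(n_snps)]
    ld_df = pd.DataFrame(ld, index=snp_ids, columns=snp_ids)

    mqtl_rows = []
    true_ge = {}
    for (snp, cpg), b_true in sorted(config.mqtl_effects.items()):
        snp, cpg = int(snp), int(cpg)
        se = 1.0 / math.sqrt(2.0 * eaf[snp] * (1.0 - eaf[snp]) * config.mqtl_sample_size)
        bhat = b_true + (rng.normal(0.0, se) if config.summary_noise else 0.0)
        z = bhat / se
        mqtl_rows.append(
            {
                "snp": _snp_name(snp), "chrom": str(snp_chrom[snp]), "pos": int(snp_pos[snp]),
                "effect_allele": ea[snp], "other_allele": oa[snp], "eaf": eaf[snp],
                "beta": bhat, "se": se, "pval": 2.0 * stats.norm.sf(abs(z)),
                "cpg": _cpg_name(cpg),
            }
        )
        true_ge[(snp, cpg)] = b_true
    mqtl_df = pd.DataFrame(mqtl_rows)

    trait_effects: dict[int, dict[int, float]] = {0: dict(config.causal_cpg_effects_on_outcome)}
    gwas_rows = []
    for t in range(config.n_traits):
        theta = trait_effects.get(t, {})
        for snp in range(n_snps):
            b_true = sum(
                th * true_ge.get((snp, cpg), 0.0) for cpg, th in theta.items()
            )
            se = 1.0 / math.sqrt(2.0 * eaf[snp] * (1.0 - eaf[snp]) * config.gwas_sample_size)
            bhat = b_true + (rng.normal(0.0, se) if config.summary_noise else 0.0)
            z = bhat / se
            gwas_rows.append(
                {
                    "snp": _snp_name(snp), "chrom": str(snp_chrom[snp]), "pos": int(snp_pos[snp]),
                    "effect_allele": ea[snp], "other_allele": oa[snp], "eaf": eaf[snp],
                    "beta": bhat, "se": se, "pval": 2.0 * stats.norm.sf(abs(z)),
                    "trait_id": f"trait{t:03d}",
                }
            )
    gwas_df = pd.DataFrame(gwas_rows)

    truth = _truth_from_config(config)
    return mqtl_df, gwas_df, ld_df, truth
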