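"""End-to-end orchestration: simulate → EWAS → meta → regions →
persistence → MR → mediation, with per-stage TSV outputs and a manifest.

The master seed deterministically spawns one seed per stage (and per
cohort), so any stage can be rerun in isolation from the previous stage's
files and still reproduce byte-identical output.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ewas import fit_dose_response, fit_ewas, fit_negative_control, restrict_never_smokers
from .fileio import (
    PipelineConfig,
    sha256_file,
    simulation_config_from_mapping,
    write_cohort_bundle,
    write_table,
    write_truth,
)
from .mediation import fit_mediation_models, proportion_mediated, quasi_bayesian_mediate
from .meta import apply_threshold, ivw_meta, regions_to_frame, select_leading_cpgs
from .mr import mr_scan, select_and_clump
from .persistence import fit_gls_persistence, residualize
from .simulate import simulate_cohort, simulate_mr_inputs, simulate_second_timepoint

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "DEFAULT_SCENARIO"]

#: Planted-truth scenario used when the config supplies no generator
#: settings: a handful of exposure-responsive CpGs at published effect
#: magnitudes, one dose-dependent site, partial persistence, SNP
#: instruments for two CpGs, and an outcome 40% mediated through cpg00000.
DEFAULT_SCENARIO = {
    "n_samples": 600,
    "n_cpgs": 30,
    "effect_sizes": {0: 0.05, 1: 0.02, 5: -0.03},
    "dose_slopes": {0: 0.004},
    "persistence_fractions": {0: 0.6, 1: 1.0},
    "n_snps": 6,
    "mqtl_effects": {(0, 0): 0.6, (1, 1): 0.55, (2, 5): 0.5, (3, 5): 0.52},
    "causal_cpg_effects_on_outcome": {0: 4.0},
    "direct_exposure_effect_on_outcome": 0.3,
}


def _stage_seed(master: int, stage: int, extra: int = 0) -> int:
    ss = np.random.SeedSequence([master, stage, extra])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages and return the run directory.

    Writes each stage's tables under ``<out_dir>/``, a ``manifest.yaml``
    with content hashes, row counts, seeds, and the package version, and
    a ``run.log``-style stage listing inside the manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "inputs": {},
    }

    def record_stage(name: str, paths: list[Path], rows: dict[str, int], seed: int | None = None):
        manifest["stages"][name] = {
            "outputs": {p.name: sha256_file(p) for p in sorted(paths)},
            "rows": rows,
            "seed": seed,
        }

    # ---- stage 1: simulate ------------------------------------------------
    scenario = dict(config.simulate) if config.simulate else dict(DEFAULT_SCENARIO)
    bundles = []
    sim_paths: list[Path] = []
    truth = None
    sim_cfgs = []
    for c in range(config.n_cohorts):
        cfg = simulation_config_from_mapping(
            {**scenario, "seed": _stage_seed(config.seed, 1, c)}, seed=config.seed
        )
        bundle, truth_c = simulate_cohort(cfg)
        bundles.append(bundle)
        sim_cfgs.append(cfg)
        if truth is None:
            truth = truth_c
        sim_paths += list(write_cohort_bundle(bundle, out / "simulate", f"cohort{c + 1}").values())
    bundle2 = None
    if config.two_timepoints:
        bundle2 = simulate_second_timepoint(bundles[0], sim_cfgs[0])
        sim_paths += list(write_cohort_bundle(bundle2, out / "simulate", "cohort1_t2").values())
    sim_paths.append(write_truth(truth, out / "simulate" / "truth.yaml"))
    record_stage("simulate", sim_paths, {"cohorts": len(bundles)}, _stage_seed(config.seed, 1))

    # ---- stage 2: per-cohort EWAS (all variants) --------------------------
    ewas_paths = []
    per_study = {}
    for c, bundle in enumerate(bundles):
        tag = f"cohort{c + 1}"
        main = fit_ewas(bundle, "maternal_smoking", config.covariate_columns)
        per_study[tag] = main
        ewas_paths.append(write_table(main, out / "ewas" / f"{tag}.main.tsv"))
        never = fit_ewas(
            restrict_never_smokers(bundle),
            "maternal_smoking",
            [c_ for c_ in config.covariate_columns if c_ != "own_smoking"],
            model_tag="ewas_never_smokers",
        )
        ewas_paths.append(write_table(never, out / "ewas" / f"{tag}.never_smokers.tsv"))
        dose = fit_dose_response(bundle, config.covariate_columns)
        ewas_paths.append(write_table(dose, out / "ewas" / f"{tag}.dose.tsv"))
        for name, tab in fit_negative_control(bundle, config.covariate_columns).items():
            ewas_paths.append(write_table(tab, out / "ewas" / f"{tag}.negctrl_{name}.tsv"))
    record_stage("ewas", ewas_paths, {t: len(v) for t, v in per_study.items()})

    # ---- stage 3: meta-analysis -------------------------------------------
    meta = ivw_meta(per_study)
    meta_path = write_table(meta, out / "meta" / "meta.tsv")
    record_stage("meta", [meta_path], {"cpgs": len(meta)})

    # ---- stage 4: threshold + regions -------------------------------------
    sig = apply_threshold(meta, config.alpha)
    ann = bundles[0].annotation.set_index("cpg_id")
    sig = sig.join(ann[["chrom", "pos"]], on="cpg_id")
    regions = select_leading_cpgs(sig, window=config.clump_window)
    reg_df = regions_to_frame(regions)
    reg_paths = [
        write_table(sig.drop(columns=["chrom", "pos"]), out / "regions" / "significant.tsv"),
        write_table(reg_df, out / "regions" / "regions.tsv"),
    ]
    record_stage("regions", reg_paths, {"significant": len(sig), "regions": len(reg_df)})

    # ---- stage 5: persistence ---------------------------------------------
    if bundle2 is not None:
        from .persistence import technical_covariate_columns

        tech = technical_covariate_columns(bundles[0].covariates)
        res1 = residualize(bundles[0].methylation, bundles[0].covariates, tech)
        res2 = residualize(bundle2.methylation, bundle2.covariates, tech)
        pers = fit_gls_persistence(
            {"t1": res1, "t2": res2},
            bundles[0].covariates["maternal_smoking"],
            covariates={"t1": bundles[0].covariates, "t2": bundle2.covariates},
            covariate_columns=[c for c in config.covariate_columns if c in bundle2.covariates.columns],
        )
        pers_path = write_table(pers, out / "persistence" / "persistence.tsv")
        record_stage("persistence", [pers_path], {"cpgs": len(pers)})

    # ---- stage 6: Mendelian randomization ---------------------------------
    mr_cfg = dataclasses.replace(sim_cfgs[0], seed=_stage_seed(config.seed, 6))
    mqtl, gwas, ld, mr_truth = simulate_mr_inputs(mr_cfg)
    instruments = select_and_clump(
        mqtl, ld, p_threshold=config.instrument_p,
        window_bp=config.clump_window, r2_threshold=config.clump_r2,
    )
    mr_results = mr_scan(instruments, gwas, fdr_alpha=config.fdr_alpha)
    mr_paths = [
        write_table(mqtl, out / "mr" / "mqtl.tsv"),
        write_table(gwas, out / "mr" / "gwas.tsv"),
        write_table(ld.reset_index(names="snp"), out / "mr" / "ld.tsv"),
        write_table(mr_results, out / "mr" / "mr_results.tsv"),
    ]
    record_stage("mr", mr_paths, {"pairs": len(mr_results)}, _stage_seed(config.seed, 6))

    # ---- stage 7: mediation -----------------------------------------------
    mediator = config.mediator_cpg
    if mediator is None:
        causal = scenario.get("causal_cpg_effects_on_outcome", {})
        mediator = f"cpg{min(causal):05d}" if causal else bundles[0].cpg_ids[0]
    med_data = bundles[0].covariates.join(bundles[0].methylation[[mediator]])
    tech = [c for c in bundles[0].covariates.columns if c.startswith("tpc")]
    fit = fit_mediation_models(
        med_data,
        exposure="maternal_smoking",
        mediator_cpg=mediator,
        outcome=config.outcome,
        covariates=["sex", "own_smoking"] + tech,
        outcome_model=config.outcome_model,
    )
    rec = quasi_bayesian_mediate(fit, n_draws=config.mediation_draws, seed=_stage_seed(config.seed, 7))
    prop = proportion_mediated(rec)
    med_df = pd.DataFrame(
        [
            {
                "mediator": mediator,
                "outcome": config.outcome,
                "acme": rec.acme, "acme_lo": rec.acme_ci[0], "acme_hi": rec.acme_ci[1],
                "acme_pval": rec.acme_pval,
                "ade": rec.ade, "ade_lo": rec.ade_ci[0], "ade_hi": rec.ade_ci[1],
                "ade_pval": rec.ade_pval,
                "total_effect": rec.total_effect,
                "te_lo": rec.total_effect_ci[0], "te_hi": rec.total_effect_ci[1],
                "te_pval": rec.total_effect_pval,
                "prop_mediated": prop["prop_mediated"],
                "prop_lo": prop["ci"][0], "prop_hi": prop["ci"][1],
                "unstable": prop["unstable"],
                "n_draws": rec.n_draws,
            }
        ]
    )
    med_path = write_table(med_df, out / "mediation" / "mediation.tsv")
    report = out / "mediation" / "report.txt"
    with open(report, "w") as fh:
        fh.write(
            f"Mediation of {config.outcome} through {mediator}\n"
            f"  ACME  {rec.acme: .4f}  [{rec.acme_ci[0]: .4f}, {rec.acme_ci[1]: .4f}]  P={rec.acme_pval:.3g}\n"
            f"  ADE   {rec.ade: .4f}  [{rec.ade_ci[0]: .4f}, {rec.ade_ci[1]: .4f}]  P={rec.ade_pval:.3g}\n"
            f"  Total {rec.total_effect: .4f}  [{rec.total_effect_ci[0]: .4f}, {rec.total_effect_ci[1]: .4f}]"
            f"  P={rec.total_effect_pval:.3g}\n"
            f"  Proportion mediated {prop['prop_mediated']:.3f}"
            f"  [{prop['ci'][0]:.3f}, {prop['ci'][1]:.3f}]\n"
        )
    record_stage("mediation", [med_path, report], {"records": 1}, _stage_seed(config.seed, 7))

    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    logger.info("pipeline complete: %d stages -> %s", len(manifest["stages"]), out)
    return out
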