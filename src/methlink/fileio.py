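"""TSV dialects, cohort-bundle serialization, configuration, and manifests.

All tables are tab-separated with a header row and '.' as the decimal
mark; floats are serialized at 17 significant digits so a write/read
round trip is exact. CRLF line endings are accepted and normalized on
read. Genomic positions are 1-based and chromosome labels are plain
strings without a "chr" prefix.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import CohortBundle, SimulationConfig, TruthRecord

logger = logging.getLogger(__name__)

__all__ = [
    "write_table",
    "read_table",
    "write_cohort_bundle",
    "read_cohort_bundle",
    "write_truth",
    "read_truth",
    "sha256_file",
    "PipelineConfig",
    "load_pipeline_config",
    "ld_from_genotypes",
]

FLOAT_FORMAT = "%.17g"


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT, lineterminator="\n")
    return path


def read_table(path: str | Path, required: list[str] | None = None, index_col=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=index_col)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: required columns missing: {missing}")
    return df


def write_cohort_bundle(bundle: CohortBundle, directory: str | Path, prefix: str = "cohort") -> dict[str, Path]:
    """Write a bundle as three TSVs.

    The methylation matrix is written CpGs-by-samples: first column
    ``cpg_id``, remaining columns the sample ids.
    """
    directory = Path(directory)
    meth = bundle.methylation.T
    meth.index.name = "cpg_id"
    paths = {
        "methylation": write_table(meth, directory / f"{prefix}.methylation.tsv", index=True),
        "annotation": write_table(bundle.annotation, directory / f"{prefix}.annotation.tsv"),
        "covariates": write_table(
            bundle.covariates.reset_index(), directory / f"{prefix}.covariates.tsv"
        ),
    }
    return paths


def read_cohort_bundle(directory: str | Path, prefix: str = "cohort", timepoint: str = "t1") -> CohortBundle:
    directory = Path(directory)
    meth_path = directory / f"{prefix}.methylation.tsv"
    with open(meth_path) as fh:  # pandas mangles duplicate headers; check raw
        header = fh.readline().rstrip("\r\n").split("\t")
    if len(set(header[1:])) != len(header) - 1:
        raise ValueError("duplicated sample ids in methylation matrix")
    meth = read_table(meth_path, index_col=0)
    if meth.index.has_duplicates:
        raise ValueError("duplicated CpG ids in methylation matrix")
    annotation = read_table(
        directory / f"{prefix}.annotation.tsv", required=["cpg_id", "chrom", "pos", "gene"]
    )
    annotation["chrom"] = annotation["chrom"].astype(str)
    covariates = read_table(directory / f"{prefix}.covariates.tsv", required=["sample_id"])
    if covariates["sample_id"].duplicated().any():
        raise ValueError("duplicated sample ids in covariate table")
    covariates = covariates.set_index("sample_id")
    meth = meth.T
    meth.index.name = "sample_id"
    return CohortBundle(
        methylation=meth,
        annotation=annotation,
        covariates=covariates.loc[meth.index],
        timepoint=timepoint,
    )


def write_truth(truth: TruthRecord, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(truth.as_dict(), fh, sort_keys=True)
    return path


def read_truth(path: str | Path) -> TruthRecord:
    with open(path) as fh:
        return TruthRecord(**yaml.safe_load(fh))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def ld_from_genotypes(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Pairwise r from a samples × SNPs dosage matrix (0–2)."""
    g = genotypes.to_numpy(float)
    r = np.corrcoef(g, rowvar=False)
    return pd.DataFrame(r, index=genotypes.columns, columns=genotypes.columns)


@dataclasses.dataclass
class PipelineConfig:
    """All paths, covariate lists, thresholds, and seeds for one run."""

    out_dir: str = "methlink_run"
    seed: int = 0
    # synthetic generation (used when no cohort paths are given)
    simulate: dict = dataclasses.field(default_factory=dict)
    n_cohorts: int = 2
    two_timepoints: bool = True
    # existing inputs (optional; bypass simulation)
    cohort_paths: list[str] = dataclasses.field(default_factory=list)
    covariate_columns: list[str] = dataclasses.field(
        default_factory=lambda: ["sex", "bmi", "own_smoking", "social_class"]
    )
    # thresholds (epigenome-wide alpha, clumping, FDR, mediation draws)
    alpha: float = 1e-7
    clump_window: int = 1_000_000
    clump_r2: float = 0.001
    instrument_p: float = 1e-7
    fdr_alpha: float = 0.05
    mediation_draws: int = 2000
    mediator_cpg: str | None = None
    outcome: str = "outcome_continuous"
    outcome_model: str = "linear"

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha out of range: {self.alpha}")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError(f"fdr_alpha out of range: {self.fdr_alpha}")
        if self.clump_window <= 0:
            raise ValueError("clump_window must be positive")
        if not 0 <= self.clump_r2 <= 1:
            raise ValueError(f"clump_r2 out of range: {self.clump_r2}")
        if self.mediation_draws < 100:
            raise ValueError("mediation_draws must be >= 100")
        for p in self.cohort_paths:
            if not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def simulation_config_from_mapping(mapping: dict, seed: int) -> SimulationConfig:
    """Build a SimulationConfig from a YAML mapping (string keys)."""
    mapping = dict(mapping)
    for key in ("effect_sizes", "dose_slopes", "persistence_fractions", "causal_cpg_effects_on_outcome"):
        if key in mapping:
            mapping[key] = {int(k): float(v) for k, v in mapping[key].items()}
    if "mqtl_effects" in mapping:
        parsed = {}
        for k, v in mapping["mqtl_effects"].items():
            if isinstance(k, (tuple, list)):
                snp, cpg = (int(x) for x in k)
            else:  # "snp,cpg" string key from YAML
                snp, cpg = (int(x) for x in str(k).split(","))
            parsed[(snp, cpg)] = float(v)
        mapping["mqtl_effects"] = parsed
    mapping.setdefault("seed", seed)
    return SimulationConfig(**mapping)
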