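"""Bundled reference tables.

Two small published summary tables ship with the package:

* :func:`load_reported_meta` — the 69 CpGs reported as differentially
  methylated (P < 1e-7) in offspring blood after prenatal smoking
  exposure, with chromosome, 1-based position, gene label, meta-analytic
  effect (beta-value units), standard error, and P value.
* :func:`load_reported_leading_cpgs` — the 36 CpG ids reported as the
  leading (one-per-locus) sites carried into sensitivity and downstream
  analyses.

These are inputs for the region-pruning fixture: grouping the 69 sites
into 1-Mb regions must yield exactly 36 regions.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reported_meta", "load_reported_leading_cpgs"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("methlink.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def load_reported_meta() -> pd.DataFrame:
    """69 reported maternal-smoking CpGs (cpg_id, chrom, pos, gene, beta, se, pval)."""
    df = _read("reported_meta_cpgs.tsv")
    df["pos"] = df["pos"].astype(int)
    return df


def load_reported_leading_cpgs() -> pd.DataFrame:
    """36 reported leading CpGs (cpg_id, chrom, gene)."""
    return _read("reported_leading_cpgs.tsv")
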