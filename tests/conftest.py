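import numpy as np
import pandas as pd
import pytest

from methlink import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """400-sample cohort with one planted exposure effect (0.05 beta units)."""
    cfg = SimulationConfig(
        n_samples=400,
        n_cpgs=12,
        effect_sizes={0: 0.05, 3: -0.03},
        dose_slopes={1: 0.004},
        persistence_fractions={0: 0.5},
        seed=42,
    )
    bundle, truth = simulate_cohort(cfg)
    return cfg, bundle, truth


@pytest.fixture()
def toy_design():
    """Six samples, hand-checkable design: intercept + exposure + one covariate."""
    rng = np.random.default_rng(7)
    covariates = pd.DataFrame(
        {
            "exposure": [0, 0, 0, 1, 1, 1],
            "age": [20.0, 25.0, 30.0, 22.0, 28.0, 33.0],
        },
        index=pd.Index([f"S{i}" for i in range(6)], name="sample_id"),
    )
    meth = pd.DataFrame(
        rng.uniform(0.2, 0.8, size=(6, 3)),
        index=covariates.index,
        columns=["cpgA", "cpgB", "cpgC"],
    )
    return meth, covariates
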