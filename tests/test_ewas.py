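"""EWAS model checks against a brute-force normal-equations oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methlink import (
    SimulationConfig,
    fit_dose_response,
    fit_ewas,
    fit_negative_control,
    restrict_never_smokers,
    simulate_cohort,
)
from methlink.simulate import CohortBundle


def _normal_equations(X, y):
    """Independent OLS oracle: textbook (X'X)^-1 X'y with t-based se."""
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    pval = 2 * stats.t.sf(np.abs(beta / se), df)
    return beta, se, pval


def _bundle_from(meth, covariates):
    ann = pd.DataFrame(
        {"cpg_id": meth.columns, "chrom": "1", "pos": np.arange(1, meth.shape[1] + 1), "gene": ""}
    )
    return CohortBundle(methylation=meth, annotation=ann, covariates=covariates)


def test_matches_normal_equations_oracle(toy_design):
    meth, cov = toy_design
    bundle = _bundle_from(meth, cov)
    rec = fit_ewas(bundle, "exposure", ["age"]).set_index("cpg_id")
    X = np.column_stack([np.ones(6), cov["exposure"], cov["age"]])
    for cpg in meth.columns:
        beta, se, pval = _normal_equations(X, meth[cpg].to_numpy())
        assert rec.loc[cpg, "beta"] == pytest.approx(beta[1], abs=1e-10)
        assert rec.loc[cpg, "se"] == pytest.approx(se[1], abs=1e-10)
        assert rec.loc[cpg, "pval"] == pytest.approx(pval[1], abs=1e-10)


def test_pvalue_consistent_with_beta_over_se(small_cohort):
    _, bundle, _ = small_cohort
    rec = fit_ewas(bundle, "maternal_smoking", ["sex", "bmi"])
    df = rec["n"].iloc[0] - 4  # intercept + exposure + 2 covariates
    regen = 2 * stats.t.sf(np.abs(rec["beta"] / rec["se"]), df)
    np.testing.assert_allclose(rec["pval"], regen, atol=1e-12)


def test_covariate_orthogonal_to_exposure_leaves_beta_unchanged():
    """Adding a covariate orthogonal to both exposure and methylation must
    not move the exposure coefficient (noiseless projection argument)."""
    rng = np.random.default_rng(12)
    n = 12
    cov = pd.DataFrame(
        {"exposure": rng.binomial(1, 0.5, n).astype(float), "age": rng.normal(30, 5, n)},
        index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"),
    )
    meth = pd.DataFrame(
        rng.uniform(0.2, 0.8, size=(n, 3)), index=cov.index, columns=["cpgA", "cpgB", "cpgC"]
    )
    X = np.column_stack([np.ones(n), cov["exposure"], cov["age"]])
    # construct a column orthogonal to the design and to every methylation column
    q, _ = np.linalg.qr(np.column_stack([X, meth.to_numpy()]))
    ortho = rng.normal(size=n)
    ortho -= q @ (q.T @ ortho)
    assert np.abs(ortho).max() > 1e-8  # genuinely new direction
    cov2 = cov.assign(ortho=ortho)
    b0 = fit_ewas(_bundle_from(meth, cov), "exposure", ["age"]).set_index("cpg_id")["beta"]
    b1 = fit_ewas(_bundle_from(meth, cov2), "exposure", ["age", "ortho"]).set_index("cpg_id")["beta"]
    np.testing.assert_allclose(b0, b1, atol=1e-8)


def test_null_simulation_type_one_error_calibrated():
    """Under the global null, about 5% of CpGs reach P<0.05."""
    cfg = SimulationConfig(n_samples=300, n_cpgs=2000, noise_sd=0.02, seed=100)
    bundle, _ = simulate_cohort(cfg)
    rec = fit_ewas(bundle, "maternal_smoking", ["sex", "bmi", "own_smoking"])
    rate = (rec["pval"] < 0.05).mean()
    se = np.sqrt(0.05 * 0.95 / 2000)
    assert abs(rate - 0.05) < 3.2 * se


def test_rank_deficient_design_names_columns(toy_design):
    meth, cov = toy_design
    cov2 = cov.assign(age_copy=cov["age"])
    with pytest.raises(ValueError, match="age"):
        fit_ewas(_bundle_from(meth, cov2), "exposure", ["age", "age_copy"])


def test_zero_variance_cpg_skipped(toy_design):
    meth, cov = toy_design
    meth = meth.copy()
    meth["cpgA"] = 0.5
    rec = fit_ewas(_bundle_from(meth, cov), "exposure", ["age"])
    assert "cpgA" not in set(rec["cpg_id"])
    assert {"cpgB", "cpgC"} == set(rec["cpg_id"])


class TestNeverSmokers:
    def test_count_filter(self, small_cohort):
        _, bundle, _ = small_cohort
        sub = restrict_never_smokers(bundle)
        expected = int((bundle.covariates["own_smoking"] == 0).sum())
        assert len(sub.sample_ids) == expected
        assert "own_smoking" not in sub.covariates.columns

    def test_all_never_smokers_is_identity_on_samples(self, toy_design):
        meth, cov = toy_design
        cov = cov.assign(own_smoking=0)
        sub = restrict_never_smokers(_bundle_from(meth, cov))
        assert list(sub.sample_ids) == list(meth.index)

    def test_empty_subset_rejected(self, toy_design):
        meth, cov = toy_design
        cov = cov.assign(own_smoking=1)
        with pytest.raises(ValueError, match="empty"):
            restrict_never_smokers(_bundle_from(meth, cov))


class TestDoseResponse:
    def test_times_three_scaling(self, small_cohort):
        _, bundle, _ = small_cohort
        per1 = fit_dose_response(bundle, ["sex"], cigarettes_per_unit=1.0)
        per3 = fit_dose_response(bundle, ["sex"], cigarettes_per_unit=3.0)
        np.testing.assert_allclose(per3["beta"], 3.0 * per1["beta"], rtol=1e-12)
        np.testing.assert_allclose(per3["se"], 3.0 * per1["se"], rtol=1e-12)
        np.testing.assert_allclose(per3["pval"], per1["pval"], atol=1e-12)

    def test_slope_recovery_in_sd_units(self):
        """Planted per-cigarette slope recovered on the SD scale (x3)."""
        rng = np.random.default_rng(0)
        n = 4000
        cigs = np.where(rng.uniform(size=n) < 0.2, rng.poisson(3, size=n) + 1.0, 0.0)
        y = 0.01 * cigs + rng.normal(0, 0.02, size=n)
        meth = pd.DataFrame({"cpgX": y}, index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"))
        cov = pd.DataFrame({"cigs_per_day": cigs, "sex": rng.binomial(1, 0.5, n)}, index=meth.index)
        rec = fit_dose_response(_bundle_from(meth, cov), ["sex"]).set_index("cpg_id")
        expected = 3 * 0.01 / y.std(ddof=1)
        assert rec.loc["cpgX", "beta"] == pytest.approx(expected, rel=0.1)

    def test_all_zero_dose_rejected(self, toy_design):
        meth, cov = toy_design
        cov = cov.assign(cigs_per_day=0.0)
        with pytest.raises(ValueError, match="[Zz]ero-variance dose"):
            fit_dose_response(_bundle_from(meth, cov), [])


class TestNegativeControl:
    def test_zero_shared_environment_adjustment_is_noop(self):
        """With paternal smoking independent of maternal smoking and no
        paternal effect, adjusting for it leaves maternal betas unchanged
        in the noiseless case."""
        rng = np.random.default_rng(3)
        n = 400
        mat = rng.binomial(1, 0.3, n).astype(float)
        pat = rng.binomial(1, 0.3, n).astype(float)
        y = 0.4 + 0.05 * mat  # exact linear function of maternal only
        meth = pd.DataFrame({"cpgX": y}, index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"))
        cov = pd.DataFrame({"maternal_smoking": mat, "paternal_smoking": pat}, index=meth.index)
        tabs = fit_negative_control(_bundle_from(meth, cov), [])
        b_m = tabs["maternal"].set_index("cpg_id").loc["cpgX", "beta"]
        b_adj = tabs["maternal_adj_paternal"].set_index("cpg_id").loc["cpgX", "beta"]
        assert b_m == pytest.approx(0.05, abs=1e-10)
        assert b_adj == pytest.approx(b_m, abs=1e-6)

    def test_paternal_effects_smaller_under_shared_environment_only(self):
        """Confounding-only paternal path: paternal betas shrink toward the
        shared-environment fraction of the maternal effect."""
        cfg = SimulationConfig(
            n_samples=1200, n_cpgs=4, effect_sizes={0: 0.05, 1: 0.03},
            paternal_shared_env_corr=0.4, seed=21,
        )
        bundle, _ = simulate_cohort(cfg)
        tabs = fit_negative_control(bundle, ["sex", "bmi"])
        m = tabs["maternal"].set_index("cpg_id")
        p = tabs["paternal"].set_index("cpg_id")
        planted = ["cpg00000", "cpg00001"]
        assert (p.loc[planted, "beta"].abs() < m.loc[planted, "beta"].abs()).all()

    def test_constant_paternal_indicator_rejected(self, toy_design):
        meth, cov = toy_design
        cov = cov.assign(maternal_smoking=cov["exposure"], paternal_smoking=1)
        with pytest.raises(ValueError, match="constant"):
            fit_negative_control(_bundle_from(meth, cov), [])

    def test_perfect_collinearity_rejected(self, toy_design):
        meth, cov = toy_design
        cov = cov.assign(maternal_smoking=cov["exposure"], paternal_smoking=cov["exposure"])
        with pytest.raises(ValueError, match="collinear"):
            fit_negative_control(_bundle_from(meth, cov), [])
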