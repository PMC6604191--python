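"""Two-sample MR: clumping, harmonization, Wald/IVW estimators, scan FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methlink import (
    SimulationConfig,
    harmonize,
    ivw_mr,
    mr_scan,
    select_and_clump,
    simulate_mr_inputs,
    wald_ratio,
)
from methlink.mr import CLUMP_R2, CLUMP_WINDOW_BP, INSTRUMENT_P_THRESHOLD


def _mqtl(rows):
    return pd.DataFrame(
        rows,
        columns=["snp", "cpg", "chrom", "pos", "effect_allele", "other_allele", "eaf", "beta", "se", "pval"],
    )


def _ld(snps, r=0.0):
    m = np.full((len(snps), len(snps)), r)
    np.fill_diagonal(m, 1.0)
    return pd.DataFrame(m, index=snps, columns=snps)


class TestClumping:
    def test_defaults_are_the_stated_parameters(self):
        assert INSTRUMENT_P_THRESHOLD == 1e-7
        assert CLUMP_WINDOW_BP == 1_000_000
        assert CLUMP_R2 == 0.001

    def test_single_snp_below_threshold_retained(self):
        mqtl = _mqtl([("rs1", "cpgA", "1", 100, "A", "G", 0.3, 0.5, 0.05, 1e-9)])
        inst = select_and_clump(mqtl, _ld(["rs1"]))
        assert list(inst["cpgA"].snps["snp"]) == ["rs1"]

    def test_correlated_pair_keeps_smaller_p(self):
        mqtl = _mqtl(
            [
                ("rs1", "cpgA", "1", 100, "A", "G", 0.3, 0.5, 0.05, 1e-8),
                ("rs2", "cpgA", "1", 200, "C", "T", 0.4, 0.4, 0.05, 1e-9),
            ]
        )
        inst = select_and_clump(mqtl, _ld(["rs1", "rs2"], r=np.sqrt(0.5)))
        assert list(inst["cpgA"].snps["snp"]) == ["rs2"]
        assert ("rs1", "ld") in inst["cpgA"].exclusions

    def test_above_threshold_excluded_with_reason(self):
        mqtl = _mqtl([("rs1", "cpgA", "1", 100, "A", "G", 0.3, 0.1, 0.05, 1e-3)])
        inst = select_and_clump(mqtl, _ld(["rs1"]))
        assert len(inst["cpgA"].snps) == 0
        assert ("rs1", "pval") in inst["cpgA"].exclusions

    def test_snp_absent_from_ld_matrix_reported(self):
        mqtl = _mqtl([("rs9", "cpgA", "1", 100, "A", "G", 0.3, 0.5, 0.05, 1e-9)])
        with pytest.raises(ValueError, match="rs9"):
            select_and_clump(mqtl, _ld(["rs1"]))

    def test_distant_snps_both_kept_despite_ld(self):
        mqtl = _mqtl(
            [
                ("rs1", "cpgA", "1", 100, "A", "G", 0.3, 0.5, 0.05, 1e-9),
                ("rs2", "cpgA", "1", 2_000_000, "C", "T", 0.4, 0.4, 0.05, 1e-8),
            ]
        )
        inst = select_and_clump(mqtl, _ld(["rs1", "rs2"], r=0.9))
        assert sorted(inst["cpgA"].snps["snp"]) == ["rs1", "rs2"]

    def _greedy_oracle(self, pvals, positions, ld, window, r2):
        """Independent set-based re-derivation of the clumping rule."""
        order = sorted(range(len(pvals)), key=lambda i: (pvals[i], i))
        kept, removed = [], set()
        for i in order:
            if i in removed:
                continue
            kept.append(i)
            for j in order:
                if j in removed or j in kept:
                    continue
                if abs(positions[j] - positions[i]) <= window // 2 and ld[i][j] ** 2 >= r2:
                    removed.add(j)
        return kept

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_independent_oracle_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        pos = rng.integers(1, 1_500_000, n)
        p = 10.0 ** -rng.uniform(8, 12, n)
        corr = rng.uniform(-1, 1, (n, n))
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 1.0)
        snps = [f"rs{i}" for i in range(n)]
        mqtl = _mqtl(
            [(snps[i], "cpgA", "1", int(pos[i]), "A", "G", 0.3, 0.5, 0.05, p[i]) for i in range(n)]
        )
        ld = pd.DataFrame(corr, index=snps, columns=snps)
        inst = select_and_clump(mqtl, ld, r2_threshold=0.3)
        expect = self._greedy_oracle(list(p), list(pos), corr, 1_000_000, 0.3)
        assert list(inst["cpgA"].snps["snp"]) == [snps[i] for i in expect]


def _row(snp="rs1", ea="A", oa="G", eaf=0.3, beta=0.3, se=0.05):
    return pd.Series(
        {"snp": snp, "effect_allele": ea, "other_allele": oa, "eaf": eaf, "beta": beta, "se": se}
    )


class TestHarmonize:
    def test_identical_orientation_unchanged(self):
        h, reason = harmonize(_row(), _row(beta=0.1))
        assert reason is None
        assert h["beta"] == pytest.approx(0.1)

    def test_swapped_alleles_flip_sign(self):
        h, reason = harmonize(_row(), _row(ea="G", oa="A", eaf=0.7, beta=0.3))
        assert reason is None
        assert h["beta"] == pytest.approx(-0.3)
        assert h["eaf"] == pytest.approx(0.3)

    def test_strand_flip_aligned(self):
        h, reason = harmonize(_row(ea="A", oa="G"), _row(ea="T", oa="C", beta=0.2))
        assert reason is None
        assert h["beta"] == pytest.approx(0.2)

    def test_strand_flip_and_swap(self):
        h, reason = harmonize(_row(ea="A", oa="G"), _row(ea="C", oa="T", eaf=0.7, beta=0.2))
        assert reason is None
        assert h["beta"] == pytest.approx(-0.2)

    def test_palindromic_ambiguous_eaf_excluded(self):
        h, reason = harmonize(_row(ea="A", oa="T", eaf=0.50), _row(ea="A", oa="T", eaf=0.5))
        assert h is None
        assert reason == "palindromic-ambiguous"

    def test_palindromic_resolved_by_frequency(self):
        h, reason = harmonize(_row(ea="A", oa="T", eaf=0.2), _row(ea="A", oa="T", eaf=0.8, beta=0.3))
        assert reason is None
        assert h["beta"] == pytest.approx(-0.3)

    def test_incompatible_alleles_excluded(self):
        h, reason = harmonize(_row(ea="A", oa="G"), _row(ea="A", oa="C"))
        assert h is None
        assert reason == "allele-mismatch"


class TestEstimators:
    def test_unit_instrument_identity(self):
        rec = wald_ratio(1.0, 0.1, 0.25, 0.04)
        assert rec.beta == pytest.approx(0.25)
        assert rec.se == pytest.approx(0.04)

    def test_hand_computed_wald_first_order_and_delta(self):
        rec = wald_ratio(0.2, 0.02, 0.05, 0.01)
        assert rec.beta == pytest.approx(0.25, abs=1e-10)
        assert rec.se == pytest.approx(0.05, abs=1e-10)
        delta = wald_ratio(0.2, 0.02, 0.05, 0.01, se_method="delta")
        assert delta.se == pytest.approx(0.055902, abs=1e-6)

    def test_zero_instrument_effect_rejected(self):
        with pytest.raises(ValueError, match="weak"):
            wald_ratio(0.0, 0.02, 0.05, 0.01)

    def test_hand_computed_ivw(self):
        h = pd.DataFrame(
            {"beta_exposure": [0.2, 0.1], "beta_outcome": [0.05, 0.03], "se_outcome": [0.01, 0.01]}
        )
        rec = ivw_mr(h)
        assert rec.beta == pytest.approx(0.26, abs=1e-10)
        assert rec.se == pytest.approx(0.044721, abs=1e-6)

    def test_duplicated_instrument_matches_wald_with_root2_se(self):
        h = pd.DataFrame(
            {"beta_exposure": [0.2, 0.2], "beta_outcome": [0.05, 0.05], "se_outcome": [0.01, 0.01]}
        )
        rec = ivw_mr(h)
        w = wald_ratio(0.2, 0.02, 0.05, 0.01)
        assert rec.beta == pytest.approx(w.beta, abs=1e-12)
        assert rec.se == pytest.approx(w.se / np.sqrt(2), abs=1e-12)

    def test_ivw_equals_inverse_variance_pooled_wald_ratios(self):
        rng = np.random.default_rng(4)
        h = pd.DataFrame(
            {
                "beta_exposure": rng.uniform(0.1, 0.5, 5),
                "beta_outcome": rng.normal(0, 0.05, 5),
                "se_outcome": rng.uniform(0.005, 0.02, 5),
            }
        )
        rec = ivw_mr(h)
        ratios = h["beta_outcome"] / h["beta_exposure"]
        ses = h["se_outcome"] / h["beta_exposure"].abs()
        w = 1 / ses**2
        pooled = (ratios * w).sum() / w.sum()
        assert rec.beta == pytest.approx(pooled, abs=1e-12)
        assert rec.se == pytest.approx(w.sum() ** -0.5, abs=1e-12)

    def test_ivw_requires_two_instruments(self):
        with pytest.raises(ValueError, match="2 instruments"):
            ivw_mr(pd.DataFrame({"beta_exposure": [0.2], "beta_outcome": [0.05], "se_outcome": [0.01]}))

    def test_scale_equivariance(self):
        """Multiplying exposure betas by c divides the estimate by c."""
        h = pd.DataFrame(
            {"beta_exposure": [0.2, 0.1], "beta_outcome": [0.05, 0.03], "se_outcome": [0.01, 0.01]}
        )
        c = 2.5
        h2 = h.assign(beta_exposure=h["beta_exposure"] * c)
        assert ivw_mr(h2).beta == pytest.approx(ivw_mr(h).beta / c, abs=1e-12)


def _scan_inputs(seed, theta=-0.5, n_traits=1, strength=0.6):
    cfg = SimulationConfig(
        n_cpgs=3, n_snps=2, n_traits=n_traits,
        mqtl_effects={(0, 0): strength, (1, 1): strength},
        causal_cpg_effects_on_outcome={0: theta},
        seed=seed,
    )
    return simulate_mr_inputs(cfg)


class TestScan:
    def test_single_pair_fdr_equals_raw_p(self):
        mqtl, gwas, ld, _ = _scan_inputs(3)
        gwas = gwas[gwas["snp"] == "rs000001"]  # only cpg0's instrument present
        inst = select_and_clump(mqtl, ld)
        out = mr_scan(inst, gwas)
        assert len(out) == 1
        assert out["fdr_pval"].iloc[0] == pytest.approx(out["pval"].iloc[0])

    def test_allele_flip_invariance(self):
        """Recoding the effect allele of a GWAS SNP (negated beta,
        complemented eaf) leaves every MR record unchanged."""
        mqtl, gwas, ld, _ = _scan_inputs(5)
        inst = select_and_clump(mqtl, ld)
        base = mr_scan(inst, gwas)
        flipped = gwas.copy()
        m = flipped["snp"] == "rs000001"
        flipped.loc[m, ["effect_allele", "other_allele"]] = flipped.loc[
            m, ["other_allele", "effect_allele"]
        ].to_numpy()
        flipped.loc[m, "beta"] = -flipped.loc[m, "beta"]
        flipped.loc[m, "eaf"] = 1 - flipped.loc[m, "eaf"]
        out = mr_scan(inst, flipped)
        pd.testing.assert_frame_equal(base, out)

    def test_wald_used_for_single_instrument_ivw_for_two(self):
        cfg = SimulationConfig(
            n_cpgs=2, n_snps=3,
            mqtl_effects={(0, 0): 0.6, (1, 0): 0.55, (2, 1): 0.6},
            causal_cpg_effects_on_outcome={0: -0.4},
            seed=9,
        )
        mqtl, gwas, ld, _ = simulate_mr_inputs(cfg)
        inst = select_and_clump(mqtl, ld)
        out = mr_scan(inst, gwas).set_index("cpg_id")
        assert out.loc["cpg00000", "method"] == "ivw"
        assert out.loc["cpg00000", "n_snps"] == 2
        assert out.loc["cpg00001", "method"] == "wald_ratio"

    def test_null_effects_centered_on_zero(self):
        """Valid instruments with zero causal effect: mean Wald estimate
        over seeds within 3 Monte-Carlo SEs of zero."""
        est = []
        for seed in range(120):
            mqtl, gwas, ld, _ = _scan_inputs(1000 + seed, theta=0.0)
            inst = select_and_clump(mqtl, ld)
            out = mr_scan(inst, gwas).set_index("cpg_id")
            if "cpg00000" in out.index:
                est.append(out.loc["cpg00000", "beta"])
        est = np.asarray(est)
        assert len(est) > 100
        assert abs(est.mean()) < 3 * est.std(ddof=1) / np.sqrt(len(est))

    def test_planted_effect_recovered_and_flagged(self):
        mqtl, gwas, ld, truth = _scan_inputs(7)
        inst = select_and_clump(mqtl, ld)
        out = mr_scan(inst, gwas).set_index("cpg_id")
        assert out.loc["cpg00000", "beta"] == pytest.approx(-0.5, abs=0.1)
        assert bool(out.loc["cpg00000", "significant"])
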