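"""Relative-risk components: lifestyle, family history, polygenic, combination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crcscreen.cohort import (FamilyHistoryConstellation, NO_FAMILY_HISTORY,
                              Person, RiskFactorDefinition)
from crcscreen.risk import (FamilyHistoryRule, FamilyHistoryTable,
                            GenomicDistribution, ModelComponents, RiskModelError,
                            Snp, SnpPanel, centered_snp_rrs, combine_rr,
                            enumerate_genomic_rrs, family_history_rr,
                            genomic_distribution, lifestyle_rr,
                            sample_genomic_rr)

TWO_LEVEL = RiskFactorDefinition("f", ("ref", "high"), (0.5, 0.5), (1.0, 2.0))


def person_with(levels, fh=NO_FAMILY_HISTORY):
    return Person(id="t", age=50, sex="male", factor_levels=levels,
                  family_history=fh)


class TestLifestyle:
    def test_referent_level_divided_by_mean(self):
        # mean RR = 0.5*1 + 0.5*2 = 1.5; referent contributes 1/1.5
        rr = lifestyle_rr(person_with({"f": "ref"}), [TWO_LEVEL])
        assert rr == pytest.approx(1.0 / 1.5)

    def test_elevated_level(self):
        rr = lifestyle_rr(person_with({"f": "high"}), [TWO_LEVEL])
        assert rr == pytest.approx(2.0 / 1.5)

    def test_single_level_factors_give_identity(self):
        fs = [RiskFactorDefinition(f"f{i}", ("only",), (1.0,), (1.0,))
              for i in range(3)]
        p = person_with({f.name: "only" for f in fs})
        assert lifestyle_rr(p, fs) == 1.0

    def test_missing_factor_named_in_error(self):
        with pytest.raises(RiskModelError, match="'f'"):
            lifestyle_rr(person_with({}), [TWO_LEVEL])

    def test_population_mean_is_one(self, factors):
        """Each factor's expected contribution under its prevalences is 1."""
        for f in factors:
            mean = sum(p * (r / f.mean_rr()) for p, r in zip(f.prevalences, f.rrs))
            assert mean == pytest.approx(1.0, abs=1e-12)


class TestFamilyHistory:
    TOY = FamilyHistoryTable(rules=(
        FamilyHistoryRule(rr=6.5, min_fdr=2),
        FamilyHistoryRule(rr=3.0, min_fdr=1, dx_before=55),
    ))

    def test_no_history_gets_default(self):
        assert family_history_rr(person_with({}), self.TOY) == 1.0

    def test_first_matching_rule_wins(self):
        fh = FamilyHistoryConstellation(n_fdr=1, youngest_dx_age=50)
        assert family_history_rr(person_with({}, fh), self.TOY) == 3.0

    def test_two_fdr_rule(self):
        fh = FamilyHistoryConstellation(n_fdr=2, youngest_dx_age=60)
        assert family_history_rr(person_with({}, fh), self.TOY) == 6.5

    def test_late_diagnosis_misses_dx_rule(self):
        fh = FamilyHistoryConstellation(n_fdr=1, youngest_dx_age=60)
        assert family_history_rr(person_with({}, fh), self.TOY) == 1.0


ONE_SNP = SnpPanel((Snp("rs1", 0.5, 2.0),))


class TestGenomicDistribution:
    def test_single_snp_centered_rrs(self):
        # E[OR^g] = 0.25 + 0.5*2 + 0.25*4 = 2.25
        rrs, probs = centered_snp_rrs(ONE_SNP.snps[0])
        assert rrs == pytest.approx([1 / 2.25, 2 / 2.25, 4 / 2.25])
        assert float(probs @ rrs) == pytest.approx(1.0, abs=1e-15)

    def test_single_snp_sigma2(self):
        # Var(g) * ln(2)^2 = 0.5 * 0.6931^2
        dist = genomic_distribution(ONE_SNP)
        assert dist.sigma2 == pytest.approx(0.5 * np.log(2.0) ** 2)

    def test_null_panel_degenerate(self):
        null = SnpPanel(tuple(Snp(f"s{i}", 0.3, 1.0) for i in range(5)))
        assert genomic_distribution(null).sigma2 == 0.0
        assert np.all(sample_genomic_rr(null, 100, 0, "exact") == 1.0)

    def test_sigma2_additive_over_concatenated_panels(self, panel):
        half1 = SnpPanel(panel.snps[:20])
        half2 = SnpPanel(panel.snps[20:])
        total = (genomic_distribution(half1).sigma2
                 + genomic_distribution(half2).sigma2)
        assert genomic_distribution(panel).sigma2 == pytest.approx(total)

    def test_centered_flag_requires_mu_consistency(self):
        with pytest.raises(RiskModelError):
            GenomicDistribution(mu=0.1, sigma2=0.2, centered=True)

    def test_empty_panel_rejected(self):
        with pytest.raises(RiskModelError, match="empty"):
            SnpPanel(())


class TestGenomicSampling:
    def test_sample_mean_rr_near_one(self, panel):
        n = 50_000
        rr = sample_genomic_rr(panel, n, 123, "exact")
        assert abs(rr.mean() - 1.0) < 5 * rr.std() / np.sqrt(n)

    def test_exact_matches_enumeration_two_snps(self):
        """Exact sampler frequencies fit the brute-force 3^k distribution."""
        from scipy.stats import chisquare
        small = SnpPanel((Snp("a", 0.3, 1.8), Snp("b", 0.6, 1.3)))
        support, probs = enumerate_genomic_rrs(small)
        draws = sample_genomic_rr(small, 20_000, 42, "exact")
        order = np.argsort(support)
        svals, sprobs = support[order], probs[order]
        pos = np.clip(np.searchsorted(svals, draws), 0, svals.size - 1)
        left = np.clip(pos - 1, 0, svals.size - 1)
        idx = np.where(np.abs(svals[left] - draws) < np.abs(svals[pos] - draws),
                       left, pos)
        counts = np.bincount(idx, minlength=support.size)
        assert chisquare(counts, sprobs * draws.size).pvalue > 0.001

    def test_seed_reproducibility(self, panel):
        a = sample_genomic_rr(panel, 100, 9, "lognormal")
        b = sample_genomic_rr(panel, 100, 9, "lognormal")
        assert np.array_equal(a, b)

    def test_unknown_method_rejected(self, panel):
        with pytest.raises(RiskModelError, match="unknown sampling method"):
            sample_genomic_rr(panel, 10, 0, "bootstrap")


class TestCombine:
    def test_identity(self):
        assert combine_rr(1.0, 1.0, 1.0) == 1.0

    def test_product_on_log_additive_scale(self):
        assert combine_rr(1.2, 1.5, 2.0) == pytest.approx(3.6)

    def test_disabled_component_contributes_factor_one(self):
        comp = ModelComponents(use_genomic=False)
        assert combine_rr(1.2, 1.5, 2.0, comp) == pytest.approx(2.4)

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(RiskModelError):
            combine_rr(1.0, -0.5, 1.0)

    def test_all_components_disabled_rejected(self):
        with pytest.raises(RiskModelError):
            ModelComponents(False, False, False)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.1, 10), st.floats(0.1, 10), st.floats(0.1, 10))
    def test_multiplicative_decomposition(self, a, b, c):
        """combine(a,b,1) * combine(1,1,c) == combine(a,b,c)."""
        whole = combine_rr(a, b, c)
        parts = combine_rr(a, b, 1.0) * combine_rr(1.0, 1.0, c)
        assert parts == pytest.approx(whole, rel=1e-12)


class TestPanelIO:
    def test_tsv_round_trip(self, tmp_path, panel):
        path = tmp_path / "panel.tsv"
        panel.to_tsv(path)
        assert SnpPanel.from_tsv(path) == panel

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\traf\nrs1\t0.5\n")
        with pytest.raises(RiskModelError, match="or_per_allele"):
            SnpPanel.from_tsv(path)
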