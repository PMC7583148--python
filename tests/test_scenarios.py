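"""Scenario assignment semantics and threshold calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crcscreen.cohort import Person
from crcscreen.scenarios import (AgeRule, Assignment, CalibrationError,
                                 ScenarioDefinition, ScenarioError, assign_vec,
                                 assign_category_scenario,
                                 assign_threshold_scenario, calibrate_thresholds,
                                 default_age_rules, fh_category,
                                 reference_targets, scenario_s1, scenario_s2,
                                 scenario_s3, scenario_s4)


def person(age=50, sex="male"):
    return Person(id="t", age=age, sex=sex)


class TestFhCategory:
    @pytest.mark.parametrize("rr,cat", [
        (0.5, 1), (2.0, 1),   # boundary inclusive in lower category
        (2.01, 2), (3.0, 2), (6.0, 2),
        (6.01, 3), (7.0, 3),
    ])
    def test_guideline_bounds(self, rr, cat):
        assert fh_category(rr) == cat

    def test_nonpositive_rejected(self):
        with pytest.raises(ScenarioError):
            fh_category(0.0)


class TestCategoryAssignment:
    def test_s4_male_boundary_in_lower_category(self):
        a = assign_category_scenario(person(sex="male"), 2.5, scenario_s4())
        assert a.category == "1a"

    def test_s4_female_same_rr_different_category(self):
        a = assign_category_scenario(person(sex="female"), 2.5, scenario_s4())
        assert a.category == "1a"  # female 1a spans (2, 3.5]

    def test_s4_sex_specific_bounds_differ(self):
        male = assign_category_scenario(person(sex="male"), 1.8, scenario_s4())
        female = assign_category_scenario(person(sex="female"), 1.8, scenario_s4())
        assert (male.category, female.category) == ("1a", "1")

    def test_s3_low_risk_below_screening_age(self):
        a = assign_category_scenario(person(age=45), 1.0, scenario_s3())
        assert a.modality == "none" and a.interval_years is None

    def test_s3_category1_screens_from_50(self):
        a = assign_category_scenario(person(age=50), 1.0, scenario_s3())
        assert (a.modality, a.interval_years) == ("iFOBT", 2)

    def test_category2_colonoscopy_from_50(self):
        a = assign_category_scenario(person(age=55), 3.0, scenario_s3())
        assert (a.modality, a.interval_years) == ("colonoscopy", 5)

    def test_category3_earliest_screening(self):
        a = assign_category_scenario(person(age=35), 7.0, scenario_s1())
        assert (a.modality, a.interval_years) == ("iFOBT", 2)

    def test_missing_sex_bounds_rejected(self):
        sc = ScenarioDefinition(
            id="X", kind="category_rr",
            category_bounds={"male": (("1", 2.0), ("2", math.inf))},
            age_rules=default_age_rules())
        with pytest.raises(ScenarioError, match="female"):
            assign_category_scenario(person(sex="female"), 1.0, sc)


class TestThresholdAssignment:
    S2 = scenario_s2()

    def test_above_colonoscopy_threshold(self):
        a = assign_threshold_scenario(person(), 0.05, self.S2)
        assert a.modality == "colonoscopy"

    def test_between_thresholds(self):
        a = assign_threshold_scenario(person(), 0.02, self.S2)
        assert a.modality == "iFOBT"

    def test_exactly_at_threshold_not_screened(self):
        """Strict 'exceeds': 0.9% exactly stays unscreened."""
        a = assign_threshold_scenario(person(), 0.009, self.S2)
        assert a.modality == "none" and a.interval_years is None

    def test_risk_outside_unit_interval_rejected(self):
        with pytest.raises(ScenarioError):
            assign_threshold_scenario(person(), 1.5, self.S2)


class TestScenarioValidation:
    def test_bounds_must_increase(self):
        with pytest.raises(ScenarioError, match="increasing"):
            ScenarioDefinition(id="X", kind="category_rr",
                               category_bounds={None: (("1", 6.0), ("2", 2.0),
                                                       ("3", math.inf))})

    def test_thresholds_ordered(self):
        with pytest.raises(ScenarioError):
            scenario_s2(0.04, 0.009)

    def test_overlapping_age_windows_rejected(self):
        with pytest.raises(ScenarioError, match="overlap"):
            ScenarioDefinition(
                id="X", kind="category_rr",
                category_bounds={None: (("1", math.inf),)},
                age_rules={"1": (AgeRule(50, 74, "iFOBT", 2),
                                 AgeRule(60, 70, "colonoscopy", 5))})

    def test_none_assignment_cannot_carry_interval(self):
        with pytest.raises(ScenarioError):
            Assignment("p", "S1", "1", "none", 2)


class TestVectorisedAssignment:
    def test_matches_scalar_api(self):
        sc = scenario_s4()
        rng = np.random.default_rng(0)
        ages = rng.integers(35, 75, 200)
        sex_codes = rng.integers(0, 2, 200)
        rrs = rng.lognormal(0, 0.7, 200)
        mods, cats = assign_vec(sc, ages, sex_codes, rrs)
        for i in range(200):
            p = person(age=int(ages[i]), sex="male" if sex_codes[i] == 0 else "female")
            a = assign_category_scenario(p, float(rrs[i]), sc)
            assert mods[i] == a.modality and cats[i] == a.category

    def test_partition_every_person_one_modality(self):
        mods, _ = assign_vec(scenario_s2(), np.full(50, 60), np.zeros(50, int),
                             np.linspace(0, 0.2, 50))
        assert set(mods) <= {"none", "iFOBT", "colonoscopy"}


FORTY_RISKS = np.arange(1, 41) * 0.001  # distinct risks 0.001 .. 0.040


class TestThresholdCalibration:
    def reference(self, n_col, n_if, risks=FORTY_RISKS):
        """Order-statistic oracle target: top n_col, next n_if by risk."""
        order = np.argsort(risks)[::-1]
        groups = np.array(["none"] * len(risks), dtype=object)
        groups[order[:n_col]] = "colonoscopy"
        groups[order[n_col:n_col + n_if]] = "iFOBT"
        return reference_targets(groups, risks)

    def test_match_screeners_reproduces_order_statistics(self):
        ref = self.reference(5, 20)
        t_if, t_col = calibrate_thresholds(FORTY_RISKS, ref, "match_screeners")
        srt = np.sort(FORTY_RISKS)
        assert srt[34] < t_col < srt[35]  # between 35th and 36th order statistic
        assert int((FORTY_RISKS > t_col).sum()) == 5
        n_if = int(((FORTY_RISKS > t_if) & (FORTY_RISKS <= t_col)).sum())
        assert n_if == 20

    def test_zero_targets_screen_nobody(self):
        ref = self.reference(0, 0)
        t_if, t_col = calibrate_thresholds(FORTY_RISKS, ref, "match_screeners")
        assert t_col >= FORTY_RISKS.max()
        assert int((FORTY_RISKS > t_col).sum()) == 0
        assert int((FORTY_RISKS > t_if).sum() - (FORTY_RISKS > t_col).sum()) == 0

    def test_match_cancers_with_near_equal_risks_reduces_to_counts(self):
        """When everyone's risk is (nearly) equal, cancer shares are head
        counts, so matching cancers picks the same split as matching people."""
        risks = 0.01 + np.arange(40) * 1e-9
        ref = self.reference(5, 20, risks)
        t_if, t_col = calibrate_thresholds(risks, ref, "match_cancers")
        assert int((risks > t_col).sum()) == 5
        assert int(((risks > t_if) & (risks <= t_col)).sum()) == 20

    def test_tied_risks_make_exact_targets_unattainable(self):
        risks = np.full(40, 0.01)
        order_groups = np.array(["colonoscopy"] * 5 + ["iFOBT"] * 20 + ["none"] * 15)
        ref = reference_targets(order_groups, risks)
        with pytest.raises(CalibrationError):
            calibrate_thresholds(risks, ref, "match_cancers")

    def test_match_cancers_on_distinct_risks(self):
        ref = self.reference(5, 20)
        t_if, t_col = calibrate_thresholds(FORTY_RISKS, ref, "match_cancers")
        total = FORTY_RISKS.sum()
        share_col = FORTY_RISKS[FORTY_RISKS > t_col].sum() / total
        assert share_col == pytest.approx(ref["colonoscopy"]["cancer_share"],
                                          rel=1e-3)

    def test_unattainable_target_diagnosed(self):
        ref = self.reference(5, 20)
        ref["colonoscopy"]["people_count"] = 100  # more than cohort size
        with pytest.raises(CalibrationError, match="exceeds"):
            calibrate_thresholds(FORTY_RISKS, ref, "match_screeners")

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.floats(0.001, 0.05), st.floats(0.001, 0.05))
    def test_monotonicity_of_group_sizes(self, t_lo, t_hi):
        """Raising a threshold never grows the group above it."""
        t1, t2 = sorted((t_lo, t_hi))
        n_above_low = int((FORTY_RISKS > t1).sum())
        n_above_high = int((FORTY_RISKS > t2).sum())
        assert n_above_high <= n_above_low
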