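"""Screening scenarios: risk -> recommendation assignment and threshold calibration.

Four policy families are packaged:

* S1 — current guidelines: three categories from the family-history RR
  alone (category 1: RR <= 2; category 2: 2 < RR <= 6; category 3: RR > 6),
  each category mapping age windows to a modality.
* S2 — fully tailored: iFOBT once the 10-year absolute risk exceeds 0.9%
  and colonoscopy once it exceeds 4.0% (strict inequalities).  Variants
  S2a/S2b re-calibrate those thresholds to match S1's number of
  screeners or expected cancers per group.
* S3 — S1's category bounds and age rules, but the category is set by
  the combined (lifestyle x genomic x family-history) RR.
* S4 — as S3 with a fourth category for those slightly above average
  risk and sex-specific bounds (men: 1.5 / 2.5 / 5; women: 2 / 3.5 / 7).

Category bounds are inclusive on the upper edge; absolute thresholds are
strict ("exceeds").  All bounds and age rules are plain data and can be
overridden from config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort import AGE_MAX, AGE_MIN, Person

MODALITIES = ("none", "iFOBT", "colonoscopy")
_MOD_CODE = {m: i for i, m in enumerate(MODALITIES)}


class ScenarioError(ValueError):
    pass


class CalibrationError(RuntimeError):
    """Threshold calibration target unattainable on the given cohort."""


@dataclass(frozen=True)
class AgeRule:
    """Within [age_lo, age_hi] (inclusive) recommend ``modality`` at ``interval_years``."""

    age_lo: int
    age_hi: int
    modality: str
    interval_years: Optional[int] = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ScenarioError(f"unknown modality {self.modality!r}")
        if not (AGE_MIN <= self.age_lo <= self.age_hi <= AGE_MAX):
            raise ScenarioError(
                f"age window [{self.age_lo}, {self.age_hi}] outside [{AGE_MIN}, {AGE_MAX}]"
            )
        if self.modality == "none" and self.interval_years is not None:
            raise ScenarioError("modality 'none' cannot carry an interval")
        if self.modality != "none" and (self.interval_years is None
                                        or self.interval_years <= 0):
            raise ScenarioError("screening rules need a positive interval_years")


@dataclass(frozen=True)
class ScenarioDefinition:
    """A screening policy.

    ``kind='category_rr'`` buckets a relative risk into ordered categories
    (per sex when ``category_bounds`` has sex-specific entries) and maps
    (category, age) to a modality via ``age_rules``.  ``kind='threshold_absolute'``
    compares the 10-year absolute risk against (t_ifobt, t_colonoscopy).
    ``rr_source`` names which RR drives a category scenario.
    """

    id: str
    kind: str
    rr_source: str = "combined"  # 'combined' | 'family_history'
    # sex key None = both sexes; bounds are (label, inclusive upper) pairs,
    # the last upper being +inf
    category_bounds: Mapping[Optional[str], tuple[tuple[str, float], ...]] = field(
        default_factory=dict)
    abs_thresholds: Optional[tuple[float, float]] = None
    age_rules: Mapping[str, tuple[AgeRule, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("category_rr", "threshold_absolute"):
            raise ScenarioError(f"unknown scenario kind {self.kind!r}")
        if self.rr_source not in ("combined", "family_history"):
            raise ScenarioError(f"unknown rr_source {self.rr_source!r}")
        if self.kind == "category_rr":
            if not self.category_bounds:
                raise ScenarioError(f"scenario {self.id}: category bounds required")
            for sex, bounds in self.category_bounds.items():
                uppers = [u for _, u in bounds]
                if any(b >= a for a, b in zip(uppers[1:], uppers[:-1])):
                    raise ScenarioError(
                        f"scenario {self.id}: category bounds must be strictly increasing"
                    )
                if not math.isinf(uppers[-1]):
                    raise ScenarioError(
                        f"scenario {self.id}: last category bound must be +inf"
                    )
        else:
            if self.abs_thresholds is None:
                raise ScenarioError(f"scenario {self.id}: abs_thresholds required")
            t_if, t_col = self.abs_thresholds
            if not 0.0 < t_if < t_col < 1.0:
                raise ScenarioError(
                    f"scenario {self.id}: need 0 < t_ifobt < t_colonoscopy < 1, "
                    f"got ({t_if}, {t_col})"
                )
        for cat, rules in self.age_rules.items():
            spans = sorted((r.age_lo, r.age_hi) for r in rules)
            for (lo1, hi1), (lo2, _) in zip(spans, spans[1:]):
                if lo2 <= hi1:
                    raise ScenarioError(
                        f"scenario {self.id}, category {cat}: overlapping age windows"
                    )

    def bounds_for_sex(self, sex: str) -> tuple[tuple[str, float], ...]:
        if None in self.category_bounds:
            return self.category_bounds[None]
        if sex not in self.category_bounds:
            raise ScenarioError(
                f"scenario {self.id}: no category bounds defined for sex {sex!r}"
            )
        return self.category_bounds[sex]


@dataclass(frozen=True)
class Assignment:
    person_id: str
    scenario_id: str
    category: str
    modality: str
    interval_years: Optional[int] = None

    def __post_init__(self) -> None:
        if self.modality == "none" and self.interval_years is not None:
            raise ScenarioError("no-screening assignment cannot carry an interval")


# ---------------------------------------------------------------------------
# Category lookup
# ---------------------------------------------------------------------------

_S1_BOUNDS = (("1", 2.0), ("2", 6.0), ("3", math.inf))


def fh_category(rr_family: float) -> int:
    """Current-guideline category from the family-history RR.

    Category 1: RR <= 2; category 2: 2 < RR <= 6; category 3: RR > 6.
    Boundary values fall in the lower category.
    """
    if rr_family <= 0:
        raise ScenarioError(f"rr_family must be > 0, got {rr_family}")
    if rr_family <= 2.0:
        return 1
    if rr_family <= 6.0:
        return 2
    return 3


def _category_label(bounds: tuple[tuple[str, float], ...], rr: float) -> str:
    for label, upper in bounds:
        if rr <= upper:
            return label
    return bounds[-1][0]  # unreachable: last upper is +inf


def _modality_for_age(rules: Sequence[AgeRule], age: int):
    for r in rules:
        if r.age_lo <= age <= r.age_hi:
            return r.modality, r.interval_years
    return "none", None


def assign_category_scenario(person: Person, rr: float,
                             scenario: ScenarioDefinition) -> Assignment:
    """Assign a category-based scenario from a relative risk.

    The category comes from the (sex-specific where defined) inclusive
    upper bounds; the modality from the first age rule whose window
    contains the person's age, defaulting to no screening.
    """
    if scenario.kind != "category_rr":
        raise ScenarioError(f"scenario {scenario.id} is not category-based")
    if rr <= 0:
        raise ScenarioError(f"rr must be > 0, got {rr}")
    label = _category_label(scenario.bounds_for_sex(person.sex), rr)
    modality, interval = _modality_for_age(scenario.age_rules.get(label, ()), person.age)
    return Assignment(person.id, scenario.id, label, modality, interval)


def assign_threshold_scenario(person: Person, ten_year_risk: float,
                              scenario: ScenarioDefinition) -> Assignment:
    """Assign an absolute-threshold scenario: strict "exceeds" semantics."""
    if scenario.kind != "threshold_absolute":
        raise ScenarioError(f"scenario {scenario.id} is not threshold-based")
    if not 0.0 <= ten_year_risk <= 1.0:
        raise ScenarioError(f"10-year risk {ten_year_risk} outside [0, 1]")
    t_if, t_col = scenario.abs_thresholds
    if ten_year_risk > t_col:
        return Assignment(person.id, scenario.id, "high", "colonoscopy", 5)
    if ten_year_risk > t_if:
        return Assignment(person.id, scenario.id, "elevated", "iFOBT", 2)
    return Assignment(person.id, scenario.id, "low", "none", None)


# ---------------------------------------------------------------------------
# Vectorised assignment (bootstrap hot path)
# ---------------------------------------------------------------------------

def _modality_lookup(scenario: ScenarioDefinition,
                     labels: Sequence[str]) -> np.ndarray:
    """Modality-code table M[category_index, age - AGE_MIN]."""
    n_ages = AGE_MAX - AGE_MIN + 1
    table = np.zeros((len(labels), n_ages), dtype=np.int64)
    for ci, label in enumerate(labels):
        for age in range(AGE_MIN, AGE_MAX + 1):
            modality, _ = _modality_for_age(scenario.age_rules.get(label, ()), age)
            table[ci, age - AGE_MIN] = _MOD_CODE[modality]
    return table


def assign_vec(scenario: ScenarioDefinition, ages: np.ndarray,
               sex_codes: np.ndarray, values: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised assignment for a whole (sub)cohort.

    ``values`` is the relative risk for category scenarios and the
    10-year absolute risk for threshold scenarios.  Returns
    (modality labels, category labels) as string arrays.
    """
    n = len(values)
    if scenario.kind == "threshold_absolute":
        t_if, t_col = scenario.abs_thresholds
        codes = np.where(values > t_col, 2, np.where(values > t_if, 1, 0))
        cats = np.array(["low", "elevated", "high"])[codes]
        return np.array(MODALITIES)[codes], cats

    mod_codes = np.zeros(n, dtype=np.int64)
    cat_idx = np.zeros(n, dtype=np.int64)
    all_labels: list[str] = []
    sexes_present = ({None} if None in scenario.category_bounds
                     else set(scenario.category_bounds))
    for sex_key in sexes_present:
        bounds = scenario.category_bounds[sex_key]
        labels = [lbl for lbl, _ in bounds]
        uppers = np.array([u for _, u in bounds])
        if sex_key is None:
            mask = np.ones(n, dtype=bool)
        else:
            mask = sex_codes == (0 if sex_key == "male" else 1)
        # inclusive upper bound: first index with upper >= value
        idx = np.searchsorted(uppers, values[mask], side="left")
        lookup = _modality_lookup(scenario, labels)
        mod_codes[mask] = lookup[idx, ages[mask] - AGE_MIN]
        base = len(all_labels)
        all_labels.extend(labels)
        cat_idx[mask] = base + idx
    # collapse duplicate labels across sexes so category tallies merge
    label_arr = np.array(all_labels)[cat_idx]
    return np.array(MODALITIES)[mod_codes], label_arr


# ---------------------------------------------------------------------------
# Threshold calibration for scenarios 2a / 2b
# ---------------------------------------------------------------------------

def reference_targets(groups: Sequence[str], risks: Sequence[float]) -> dict:
    """Per-group people counts and cancer shares of an existing assignment.

    Used to express scenario 1 as the calibration target for 2a/2b.
    """
    groups_arr = np.asarray(groups)
    risks_arr = np.asarray(risks, dtype=float)
    total = float(risks_arr.sum())
    out = {}
    for g in MODALITIES:
        mask = groups_arr == g
        out[g] = {
            "people_count": int(mask.sum()),
            "cancer_share": float(risks_arr[mask].sum()) / total if total > 0 else 0.0,
        }
    return out


def _bisect_count(risks: np.ndarray, target: int, lo: float, hi: float) -> float:
    """Threshold t with count(risks > t) == target, by bisection on the step function."""
    n_above = int((risks > lo).sum())
    if n_above < target:
        raise CalibrationError(
            f"target of {target} exceeds the {n_above} persons available above {lo:g}"
        )
    if target == 0:
        return float(risks.max()) if risks.size else hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        c = int((risks > mid).sum())
        if c == target:
            return mid
        if c > target:
            lo = mid
        else:
            hi = mid
    achievable = sorted({int((risks > t).sum()) for t in (lo, hi)})
    raise CalibrationError(
        f"count target {target} unattainable (tied risks); achievable nearby "
        f"counts: {achievable}"
    )


def _bisect_cancer_share(risks: np.ndarray, total_risk: float, target: float,
                         lo: float, hi: float, rel_tol: float = 1e-3) -> float:
    """Threshold t whose above-group cancer share matches target within rel_tol."""
    best_t, best_err = hi, math.inf
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        share = float(risks[risks > mid].sum()) / total_risk
        err = abs(share - target) / target if target > 0 else abs(share)
        if err < best_err:
            best_t, best_err = mid, err
        if share > target:
            lo = mid
        else:
            hi = mid
    if best_err > rel_tol:
        raise CalibrationError(
            f"cancer-share target {target:.6f} unattainable within relative "
            f"tolerance {rel_tol:g}; best achievable error {best_err:.3g}"
        )
    return best_t


def calibrate_thresholds(risks: Sequence[float], reference: Mapping,
                         mode: str = "match_screeners") -> tuple[float, float]:
    """Find (t_ifobt, t_colonoscopy) matching a reference assignment.

    ``reference`` is the output of :func:`reference_targets` on the
    scenario-1 assignment of the same cohort.  ``match_screeners``
    equalises the number of people in the colonoscopy group and in the
    iFOBT group; ``match_cancers`` equalises each group's expected-cancer
    share (relative tolerance 1e-3).  The colonoscopy threshold is fitted
    first, then the iFOBT threshold on the remainder.
    """
    risks_arr = np.asarray(risks, dtype=float)
    if risks_arr.size == 0:
        raise CalibrationError("cannot calibrate thresholds on an empty cohort")
    hi = float(risks_arr.max()) * (1 + 1e-9) + 1e-300
    if mode == "match_screeners":
        n_col = int(reference["colonoscopy"]["people_count"])
        n_if = int(reference["iFOBT"]["people_count"])
        t_col = _bisect_count(risks_arr, n_col, 0.0, hi)
        remainder = risks_arr[risks_arr <= t_col]
        if remainder.size == 0 and n_if > 0:
            raise CalibrationError(
                f"iFOBT target of {n_if} exceeds the 0 persons left below the "
                f"colonoscopy threshold"
            )
        t_if = _bisect_count(remainder, n_if, 0.0, t_col) if remainder.size else t_col
        return t_if, t_col
    if mode == "match_cancers":
        total = float(risks_arr.sum())
        s_col = float(reference["colonoscopy"]["cancer_share"])
        s_if = float(reference["iFOBT"]["cancer_share"])
        t_col = _bisect_cancer_share(risks_arr, total, s_col, 0.0, hi)
        remainder = risks_arr[risks_arr <= t_col]
        t_if = _bisect_cancer_share(remainder, total, s_if, 0.0, t_col)
        return t_if, t_col
    raise ScenarioError(f"unknown calibration mode {mode!r}")


# ---------------------------------------------------------------------------
# Packaged default scenarios
# ---------------------------------------------------------------------------

def default_age_rules() -> dict[str, tuple[AgeRule, ...]]:
    """Category -> age-window screening rules shared by S1/S3/S4.

    Category 1: biennial iFOBT from the standard starting age of 50;
    category 2: earlier iFOBT then 5-yearly colonoscopy from 50;
    category 3: earlier again, colonoscopy from 45.  Category 1a (S4
    only) starts biennial iFOBT at 45.
    """
    return {
        "1": (AgeRule(50, 74, "iFOBT", 2),),
        "1a": (AgeRule(45, 74, "iFOBT", 2),),
        "2": (AgeRule(40, 49, "iFOBT", 2), AgeRule(50, 74, "colonoscopy", 5)),
        "3": (AgeRule(35, 44, "iFOBT", 2), AgeRule(45, 74, "colonoscopy", 5)),
    }


def scenario_s1() -> ScenarioDefinition:
    """Current guidelines: categories from family history alone."""
    return ScenarioDefinition(
        id="S1", kind="category_rr", rr_source="family_history",
        category_bounds={None: _S1_BOUNDS}, age_rules=default_age_rules())


def scenario_s2(t_ifobt: float = 0.009, t_colonoscopy: float = 0.040,
                id: str = "S2") -> ScenarioDefinition:
    """Absolute-risk thresholds: iFOBT above 0.9%, colonoscopy above 4.0%."""
    return ScenarioDefinition(id=id, kind="threshold_absolute",
                              abs_thresholds=(t_ifobt, t_colonoscopy))


def scenario_s3() -> ScenarioDefinition:
    """S1's bounds and age rules driven by the combined RR."""
    return ScenarioDefinition(
        id="S3", kind="category_rr", rr_source="combined",
        category_bounds={None: _S1_BOUNDS}, age_rules=default_age_rules())


def scenario_s4() -> ScenarioDefinition:
    """Four categories with sex-specific combined-RR bounds."""
    male = (("1", 1.5), ("1a", 2.5), ("2", 5.0), ("3", math.inf))
    female = (("1", 2.0), ("1a", 3.5), ("2", 7.0), ("3", math.inf))
    return ScenarioDefinition(
        id="S4", kind="category_rr", rr_source="combined",
        category_bounds={"male": male, "female": female},
        age_rules=default_age_rules())


def default_scenarios() -> list[ScenarioDefinition]:
    return [scenario_s1(), scenario_s2(), scenario_s3(), scenario_s4()]
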