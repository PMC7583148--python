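"""Relative-to-absolute risk conversion against a population incidence table.

A person's 10-year absolute CRC risk at age a is

    P = 1 - exp(-RR * sum_{t=a}^{a+9} h0(t, sex))

where h0 is a baseline hazard obtained by dividing the population
incidence rate by the cohort-mean combined RR, so the cohort-average
hazard reproduces the population incidence (calibration).  Competing
mortality is ignored: this is a pure cause-specific cumulative risk over
the half-open age window [a, a+10).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import AGE_MAX, AGE_MIN, SEXES

WINDOW_YEARS = 10


class AbsoluteRiskError(ValueError):
    pass


@dataclass(frozen=True)
class IncidenceTable:
    """Annual CRC incidence per person-year by single year of age and sex.

    Coverage must extend from 35 to at least ``AGE_MAX + 9`` so every
    10-year window starting in the cohort age range is computable.
    """

    rates: Mapping[tuple[int, str], float]

    def __post_init__(self) -> None:
        ages = sorted({a for a, _ in self.rates})
        if not ages:
            raise AbsoluteRiskError("incidence table is empty")
        lo, hi = ages[0], ages[-1]
        if lo > AGE_MIN or hi < AGE_MAX + WINDOW_YEARS - 1:
            raise AbsoluteRiskError(
                f"incidence coverage [{lo}, {hi}] must span "
                f"[{AGE_MIN}, {AGE_MAX + WINDOW_YEARS - 1}]"
            )
        for a in range(lo, hi + 1):
            for s in SEXES:
                if (a, s) not in self.rates:
                    raise AbsoluteRiskError(f"incidence table missing (age={a}, sex={s})")
                if self.rates[(a, s)] < 0:
                    raise AbsoluteRiskError(f"negative rate at (age={a}, sex={s})")

    @property
    def min_age(self) -> int:
        return min(a for a, _ in self.rates)

    @property
    def max_age(self) -> int:
        return max(a for a, _ in self.rates)

    def rate(self, age: int, sex: str) -> float:
        try:
            return self.rates[(age, sex)]
        except KeyError:
            raise AbsoluteRiskError(f"incidence table has no (age={age}, sex={sex})") from None

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IncidenceTable":
        for col in ("age", "sex", "rate_per_person_year"):
            if col not in df.columns:
                raise AbsoluteRiskError(f"incidence table missing column {col!r}")
        return cls({(int(r.age), str(r.sex)): float(r.rate_per_person_year)
                    for r in df.itertuples(index=False)})

    @classmethod
    def from_csv(cls, path) -> "IncidenceTable":
        return cls.from_frame(pd.read_csv(path))

    def to_csv(self, path) -> None:
        rows = sorted(self.rates.items())
        pd.DataFrame(
            {"age": [a for (a, _), _ in rows],
             "sex": [s for (_, s), _ in rows],
             "rate_per_person_year": [r for _, r in rows]}
        ).to_csv(path, index=False, lineterminator="\n")

    def cum_hazard_10(self, age: int, sex: str) -> float:
        """Cumulative baseline hazard over ages [age, age+10)."""
        return float(sum(self.rate(t, sex) for t in range(age, age + WINDOW_YEARS)))


@dataclass(frozen=True)
class CalibratedBaseline:
    """Baseline hazard = incidence / mean RR, per (age, sex) cell.

    With global calibration ``mean_rr_used`` is the cohort arithmetic
    mean of combined RRs; with stratified calibration each (age, sex)
    cell is divided by that cell's own mean RR (empty cells fall back to
    the global mean) and ``mean_rr_used`` records the global mean.
    """

    incidence: IncidenceTable
    mean_rr_used: float
    cell_mean_rr: Optional[Mapping[tuple[int, str], float]] = None

    def __post_init__(self) -> None:
        if self.mean_rr_used <= 0:
            raise AbsoluteRiskError("mean_rr_used must be > 0")

    def rate(self, age: int, sex: str) -> float:
        divisor = self.mean_rr_used
        if self.cell_mean_rr is not None:
            divisor = self.cell_mean_rr.get((age, sex), self.mean_rr_used)
        return self.incidence.rate(age, sex) / divisor

    def cum_hazard_10(self, age: int, sex: str) -> float:
        return float(sum(self.rate(t, sex) for t in range(age, age + WINDOW_YEARS)))

    def cum_hazard_table(self) -> np.ndarray:
        """Array H[sex_code, age - AGE_MIN] of 10-year cumulative hazards."""
        out = np.empty((2, AGE_MAX - AGE_MIN + 1))
        for si, sex in enumerate(SEXES):
            for age in range(AGE_MIN, AGE_MAX + 1):
                out[si, age - AGE_MIN] = self.cum_hazard_10(age, sex)
        return out


def calibrate_baseline(incidence: IncidenceTable,
                       cohort_rrs: Sequence[float],
                       ages: Optional[Sequence[int]] = None,
                       sexes: Optional[Sequence[str]] = None,
                       mode: str = "global") -> CalibratedBaseline:
    """Divide the incidence table by the cohort-mean RR.

    ``mode='stratified'`` divides each (age, sex) cell by the mean RR of
    cohort members in that cell instead (requires ``ages``/``sexes``).
    """
    rrs = np.asarray(cohort_rrs, dtype=float)
    if rrs.size == 0:
        raise AbsoluteRiskError("cannot calibrate against an empty cohort")
    if np.any(rrs <= 0):
        raise AbsoluteRiskError("all cohort RRs must be > 0")
    mean_rr = float(rrs.mean())
    if mode == "global":
        return CalibratedBaseline(incidence, mean_rr)
    if mode == "stratified":
        if ages is None or sexes is None:
            raise AbsoluteRiskError("stratified calibration requires ages and sexes")
        cell: dict[tuple[int, str], list[float]] = {}
        for a, s, r in zip(ages, sexes, rrs):
            cell.setdefault((int(a), s), []).append(float(r))
        cell_mean = {k: float(np.mean(v)) for k, v in cell.items()}
        return CalibratedBaseline(incidence, mean_rr, cell_mean_rr=cell_mean)
    raise AbsoluteRiskError(f"unknown calibration mode {mode!r}")


def ten_year_risk(age: int, sex: str, rr: float,
                  baseline: CalibratedBaseline) -> float:
    """Absolute 10-year risk 1 - exp(-rr * cumulative baseline hazard)."""
    if rr < 0:
        raise AbsoluteRiskError(f"rr must be >= 0, got {rr}")
    return float(-np.expm1(-rr * baseline.cum_hazard_10(age, sex)))


def ten_year_risk_vec(ages: np.ndarray, sex_codes: np.ndarray, rrs: np.ndarray,
                      cum_hazard: np.ndarray) -> np.ndarray:
    """Vectorised 10-year risks from a precomputed hazard table.

    ``cum_hazard`` is the array from :meth:`CalibratedBaseline.cum_hazard_table`.
    """
    h = cum_hazard[sex_codes, ages - AGE_MIN]
    return -np.expm1(-rrs * h)


GROUPS = ("none", "iFOBT", "colonoscopy")


def expected_cancer_shares(risks: Sequence[float],
                           groups: Sequence[str]) -> dict[str, tuple[float, float]]:
    """Per screening group: (share of people, share of expected 10-year cancers).

    ``groups`` assigns each person to exactly one of none / iFOBT /
    colonoscopy.  Cancer shares weight each person by their absolute
    10-year risk; both share families sum to 1 across groups.
    """
    risks_arr = np.asarray(risks, dtype=float)
    if risks_arr.size == 0:
        raise AbsoluteRiskError("empty cohort")
    if np.any(np.isnan(risks_arr)):
        raise AbsoluteRiskError("some persons have unset 10-year risk")
    groups_arr = np.asarray(groups)
    if groups_arr.size != risks_arr.size:
        raise AbsoluteRiskError("every person must be assigned to exactly one group")
    unknown = set(np.unique(groups_arr)) - set(GROUPS)
    if unknown:
        raise AbsoluteRiskError(f"unknown group label(s) {sorted(unknown)}")
    n = risks_arr.size
    total_risk = float(risks_arr.sum())
    out: dict[str, tuple[float, float]] = {}
    for g in GROUPS:
        mask = groups_arr == g
        people = float(mask.sum()) / n
        cancers = float(risks_arr[mask].sum()) / total_risk if total_risk > 0 else 0.0
        out[g] = (people, cancers)
    return out
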