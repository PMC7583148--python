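"""Synthetic cohort generation and cohort file I/O.

The analysis needs a general-population control sample of people aged
35-74 with lifestyle-factor levels and a family-history constellation.
No public dataset provides this, so the package generates synthetic
cohorts whose marginal distributions are configurable: each lifestyle
factor is drawn independently from its stated level prevalences, family
history from a finite constellation distribution concentrated on "no
family history", and age/sex from configurable marginals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

AGE_MIN = 35
AGE_MAX = 74
SEXES = ("male", "female")

_PROB_TOL = 1e-9


class CohortValidationError(ValueError):
    """Raised when a cohort spec, person or cohort file violates an invariant."""


@dataclass(frozen=True)
class RiskFactorDefinition:
    """One categorical lifestyle risk factor.

    ``prevalences`` are population level frequencies; ``rrs`` are the
    relative risks per level, with at least one referent level at RR 1.0.
    """

    name: str
    levels: tuple[str, ...]
    prevalences: tuple[float, ...]
    rrs: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise CohortValidationError("factor name must be non-empty")
        n = len(self.levels)
        if n == 0:
            raise CohortValidationError(f"factor {self.name!r}: no levels")
        if len(self.prevalences) != n or len(self.rrs) != n:
            raise CohortValidationError(
                f"factor {self.name!r}: levels, prevalences and rrs must have "
                f"equal length (got {n}, {len(self.prevalences)}, {len(self.rrs)})"
            )
        if abs(sum(self.prevalences) - 1.0) > _PROB_TOL:
            raise CohortValidationError(
                f"factor {self.name!r}: prevalences sum to {sum(self.prevalences)}, not 1"
            )
        if any(p < 0 for p in self.prevalences):
            raise CohortValidationError(f"factor {self.name!r}: negative prevalence")
        if any(r <= 0 for r in self.rrs):
            raise CohortValidationError(f"factor {self.name!r}: all RRs must be > 0")
        if not any(r == 1.0 for r in self.rrs):
            raise CohortValidationError(
                f"factor {self.name!r}: at least one level must be the referent (RR 1.0)"
            )

    def mean_rr(self) -> float:
        """Population-mean RR under the stated prevalences (sum of prevalence x RR)."""
        return float(sum(p * r for p, r in zip(self.prevalences, self.rrs)))


@dataclass(frozen=True)
class FamilyHistoryConstellation:
    """Pattern of relatives affected by CRC.

    ``youngest_dx_age`` is the youngest age at diagnosis among affected
    relatives; it must be present exactly when some relative is affected.
    """

    n_fdr: int = 0
    n_sdr: int = 0
    youngest_dx_age: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_fdr < 0 or self.n_sdr < 0:
            raise CohortValidationError("relative counts must be non-negative")
        affected = self.n_fdr + self.n_sdr > 0
        if affected and self.youngest_dx_age is None:
            raise CohortValidationError(
                "youngest_dx_age required when any relative is affected"
            )
        if not affected and self.youngest_dx_age is not None:
            raise CohortValidationError(
                "youngest_dx_age must be absent when no relative is affected"
            )

    @property
    def any_affected(self) -> bool:
        return self.n_fdr + self.n_sdr > 0


NO_FAMILY_HISTORY = FamilyHistoryConstellation(0, 0, None)


@dataclass
class Person:
    id: str
    age: int
    sex: str
    factor_levels: dict[str, str] = field(default_factory=dict)
    family_history: FamilyHistoryConstellation = NO_FAMILY_HISTORY
    rr_lifestyle: Optional[float] = None
    rr_family: Optional[float] = None
    rr_genomic: Optional[float] = None
    rr_combined: Optional[float] = None

    def __post_init__(self) -> None:
        if not (AGE_MIN <= self.age <= AGE_MAX):
            raise CohortValidationError(
                f"person {self.id!r}: age {self.age} outside [{AGE_MIN}, {AGE_MAX}]"
            )
        if self.sex not in SEXES:
            raise CohortValidationError(
                f"person {self.id!r}: unknown sex {self.sex!r} (expected one of {SEXES})"
            )
        for rr_name in ("rr_lifestyle", "rr_family", "rr_genomic", "rr_combined"):
            v = getattr(self, rr_name)
            if v is not None and v <= 0:
                raise CohortValidationError(f"person {self.id!r}: {rr_name} must be > 0")


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort.

    ``age_weights`` maps each single year of age in 35-74 to a sampling
    weight (default uniform).  ``fh_distribution`` is a probability mass
    over a finite list of family-history constellations.
    """

    n: int
    factors: Sequence[RiskFactorDefinition]
    fh_distribution: Sequence[tuple[FamilyHistoryConstellation, float]]
    sex_ratio: float = 0.5  # probability of male
    age_weights: Optional[Mapping[int, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise CohortValidationError(f"cohort size n must be > 0, got {self.n}")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise CohortValidationError(f"sex_ratio must be in [0,1], got {self.sex_ratio}")
        probs = [p for _, p in self.fh_distribution]
        if abs(sum(probs) - 1.0) > _PROB_TOL:
            raise CohortValidationError(
                f"fh_distribution probabilities sum to {sum(probs)}, not 1"
            )
        if any(p < 0 for p in probs):
            raise CohortValidationError("fh_distribution has a negative probability")
        if self.age_weights is not None:
            ages = sorted(self.age_weights)
            if ages != list(range(AGE_MIN, AGE_MAX + 1)):
                raise CohortValidationError(
                    f"age_weights must cover every age in [{AGE_MIN}, {AGE_MAX}]"
                )
            total = sum(self.age_weights.values())
            if total <= 0:
                raise CohortValidationError("age_weights must have positive total mass")

    def normalized_age_probs(self) -> np.ndarray:
        ages = np.arange(AGE_MIN, AGE_MAX + 1)
        if self.age_weights is None:
            return np.full(ages.size, 1.0 / ages.size)
        w = np.array([float(self.age_weights[a]) for a in ages])
        return w / w.sum()


def generate_cohort(spec: CohortSpec) -> list[Person]:
    """Draw a synthetic cohort from ``spec``; reproducible given ``spec.seed``.

    Ages, sex, each lifestyle factor and the family-history constellation
    are sampled independently from their stated marginals.
    """
    rng = np.random.default_rng(spec.seed)
    ages = rng.choice(np.arange(AGE_MIN, AGE_MAX + 1), size=spec.n,
                      p=spec.normalized_age_probs())
    is_male = rng.random(spec.n) < spec.sex_ratio

    level_draws: dict[str, np.ndarray] = {}
    for f in spec.factors:
        idx = rng.choice(len(f.levels), size=spec.n, p=np.asarray(f.prevalences))
        level_draws[f.name] = idx

    fh_values = [c for c, _ in spec.fh_distribution]
    fh_probs = np.array([p for _, p in spec.fh_distribution])
    fh_idx = rng.choice(len(fh_values), size=spec.n, p=fh_probs)

    cohort: list[Person] = []
    for i in range(spec.n):
        cohort.append(Person(
            id=f"p{i:06d}",
            age=int(ages[i]),
            sex="male" if is_male[i] else "female",
            factor_levels={f.name: f.levels[level_draws[f.name][i]]
                           for f in spec.factors},
            family_history=fh_values[fh_idx[i]],
        ))
    return cohort


_BASE_COLUMNS = ["id", "age", "sex", "n_fdr", "n_sdr", "youngest_dx_age"]


def write_cohort(cohort: Sequence[Person], path) -> None:
    """Write a cohort to CSV (comma-separated, UTF-8, header row).

    Family history is encoded as three columns (n_fdr, n_sdr,
    youngest_dx_age with empty meaning absent); each configured factor
    gets its own column.  Output is byte-deterministic for equal cohorts.
    """
    factor_names = sorted({name for p in cohort for name in p.factor_levels})
    rows = []
    for p in cohort:
        row = {
            "id": p.id,
            "age": p.age,
            "sex": p.sex,
            "n_fdr": p.family_history.n_fdr,
            "n_sdr": p.family_history.n_sdr,
            "youngest_dx_age": ("" if p.family_history.youngest_dx_age is None
                                else p.family_history.youngest_dx_age),
        }
        row.update({name: p.factor_levels.get(name, "") for name in factor_names})
        rows.append(row)
    df = pd.DataFrame(rows, columns=_BASE_COLUMNS + factor_names)
    df.to_csv(path, index=False, lineterminator="\n")


def read_cohort(path, factors: Sequence[RiskFactorDefinition] = ()) -> list[Person]:
    """Read a cohort CSV written by :func:`write_cohort`.

    ``factors`` declares the expected factor columns; any column that is
    neither a base column nor a declared factor is rejected.
    """
    df = pd.read_csv(path, dtype={"id": str, "sex": str},
                     keep_default_na=False, na_values=[""])
    factor_names = [f.name for f in factors]
    known = set(_BASE_COLUMNS) | set(factor_names)
    for col in _BASE_COLUMNS + factor_names:
        if col not in df.columns:
            raise CohortValidationError(f"cohort file missing required column {col!r}")
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise CohortValidationError(
            f"cohort file has unknown column(s) {unknown}; expected only "
            f"{sorted(known)}"
        )
    cohort: list[Person] = []
    for rec in df.itertuples(index=False):
        dx = getattr(rec, "youngest_dx_age")
        dx_age = None if pd.isna(dx) else int(dx)
        fh = FamilyHistoryConstellation(int(rec.n_fdr), int(rec.n_sdr), dx_age)
        levels = {name: str(getattr(rec, name)) for name in factor_names}
        cohort.append(Person(id=str(rec.id), age=int(rec.age), sex=str(rec.sex),
                             factor_levels=levels, family_history=fh))
    return cohort


def make_toy_cohort() -> list[Person]:
    """Fixed 8-person cohort for tests and documentation.

    Spans both sexes and ages 35-74; includes one person with a single
    first-degree relative diagnosed before 55 and one with two affected
    first-degree relatives; everyone else has no family history.
    """
    ages = [35, 45, 50, 55, 60, 65, 70, 74]
    sexes = ["male", "female"] * 4
    fhs = [NO_FAMILY_HISTORY] * 8
    fhs[2] = FamilyHistoryConstellation(n_fdr=1, n_sdr=0, youngest_dx_age=50)
    fhs[5] = FamilyHistoryConstellation(n_fdr=2, n_sdr=0, youngest_dx_age=60)
    return [Person(id=f"toy{i}", age=a, sex=s, family_history=fh)
            for i, (a, s, fh) in enumerate(zip(ages, sexes, fhs))]


def cohort_arrays(cohort: Sequence[Person]) -> dict[str, np.ndarray]:
    """Columnar view of a cohort for vectorised downstream computation.

    Returns arrays ``age`` (int), ``sex_code`` (0 = male, 1 = female) and,
    when set on every person, ``rr_lifestyle`` / ``rr_family``.
    """
    out = {
        "age": np.array([p.age for p in cohort], dtype=np.int64),
        "sex_code": np.array([0 if p.sex == "male" else 1 for p in cohort],
                             dtype=np.int64),
    }
    for name in ("rr_lifestyle", "rr_family"):
        vals = [getattr(p, name) for p in cohort]
        if all(v is not None for v in vals):
            out[name] = np.array(vals, dtype=float)
    return out


def replace(person: Person, **changes) -> Person:
    """Functional update of a person (thin wrapper over dataclasses.replace)."""
    return dataclasses.replace(person, **changes)
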