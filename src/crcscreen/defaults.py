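"""Packaged synthetic default inputs.

Every table the pipeline consumes — lifestyle factor definitions,
family-history RR rules and constellation prevalences, the SNP panel,
the incidence table and the population projection — is configuration.
The defaults below are synthetic stand-ins with realistic magnitudes so
the package runs end to end out of the box; real tables can be
substituted through the config file.

Key anchors of the default conditions:

* cohort size 4747 (a general-population control sample), ages 35-74;
* 10 categorical lifestyle factors with modest RRs (0.7-1.5), each with
  a referent level;
* family history: 88% none, 10% one affected relative, 2% two or more;
* 45 SNPs with per-allele odds ratios in [1.05, 1.25] and risk-allele
  frequencies in [0.1, 0.9], drawn once from a fixed generator;
* incidence rising log-linearly from 3e-5/yr at age 35 to 3e-3/yr at 84,
  scaled so the sex-averaged 10-year risk at age 50 is exactly 0.9%
  (the iFOBT threshold of scenario 2 equals the average risk at the
  standard screening starting age);
* projected population of 12,221,045 persons aged 35-74.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .absolute import IncidenceTable
from .cohort import (AGE_MAX, AGE_MIN, CohortSpec, FamilyHistoryConstellation,
                     NO_FAMILY_HISTORY, RiskFactorDefinition)
from .risk import FamilyHistoryRule, FamilyHistoryTable, Snp, SnpPanel

DEFAULT_COHORT_N = 4747
DEFAULT_POPULATION_TOTAL = 12_221_045
_SNP_PANEL_DRAW_SEED = 45_002_020  # fixed: the panel is a constant fixture


def default_factors() -> list[RiskFactorDefinition]:
    """Ten generic lifestyle factors with modest, referent-anchored RRs."""
    def f(name, levels, prev, rrs):
        return RiskFactorDefinition(name, tuple(levels), tuple(prev), tuple(rrs))

    return [
        f("red_meat", ["low", "medium", "high"], [0.30, 0.50, 0.20], [1.0, 1.15, 1.35]),
        f("processed_meat", ["low", "high"], [0.65, 0.35], [1.0, 1.20]),
        f("smoking", ["never", "former", "current"], [0.55, 0.27, 0.18], [1.0, 1.10, 1.25]),
        f("alcohol", ["low", "moderate", "high"], [0.50, 0.35, 0.15], [1.0, 1.10, 1.25]),
        f("bmi", ["normal", "overweight", "obese"], [0.38, 0.36, 0.26], [1.0, 1.15, 1.35]),
        f("physical_activity", ["active", "inactive"], [0.45, 0.55], [1.0, 1.15]),
        f("aspirin", ["non_user", "user"], [0.80, 0.20], [1.0, 0.70]),
        f("diabetes", ["no", "yes"], [0.92, 0.08], [1.0, 1.30]),
        f("fruit_veg", ["high", "low"], [0.55, 0.45], [1.0, 1.10]),
        f("prior_polyp", ["no", "yes"], [0.94, 0.06], [1.0, 1.50]),
    ]


def default_family_history_table() -> FamilyHistoryTable:
    """Illustrative constellation -> RR rules (first match wins, referent 1.0).

    Magnitudes follow the usual gradient: more affected relatives,
    closer degree and younger diagnosis mean higher risk.
    """
    return FamilyHistoryTable(rules=(
        FamilyHistoryRule(rr=7.0, min_fdr=2, dx_before=55),
        FamilyHistoryRule(rr=4.0, min_fdr=2),
        FamilyHistoryRule(rr=3.0, min_fdr=1, dx_before=55),
        FamilyHistoryRule(rr=1.8, min_fdr=1),
        FamilyHistoryRule(rr=1.8, min_sdr=2),
        FamilyHistoryRule(rr=1.4, min_sdr=1),
    ), default_rr=1.0)


def default_fh_distribution() -> list[tuple[FamilyHistoryConstellation, float]]:
    """Constellation prevalences: 88% none, 10% one relative, 2% two or more."""
    return [
        (NO_FAMILY_HISTORY, 0.88),
        (FamilyHistoryConstellation(n_fdr=1, n_sdr=0, youngest_dx_age=65), 0.040),
        (FamilyHistoryConstellation(n_fdr=1, n_sdr=0, youngest_dx_age=50), 0.025),
        (FamilyHistoryConstellation(n_fdr=0, n_sdr=1, youngest_dx_age=60), 0.035),
        (FamilyHistoryConstellation(n_fdr=2, n_sdr=0, youngest_dx_age=60), 0.012),
        (FamilyHistoryConstellation(n_fdr=2, n_sdr=0, youngest_dx_age=50), 0.008),
    ]


def default_snp_panel() -> SnpPanel:
    """45 synthetic SNPs, ORs in [1.05, 1.25], RAFs in [0.1, 0.9].

    Drawn once from a fixed generator so the panel is a reproducible
    constant of the package; substitute any TSV panel via config.
    """
    rng = np.random.default_rng(_SNP_PANEL_DRAW_SEED)
    rafs = rng.uniform(0.1, 0.9, size=45)
    ors = rng.uniform(1.05, 1.25, size=45)
    return SnpPanel(tuple(
        Snp(id=f"rs_syn{i:03d}", raf=round(float(p), 4),
            or_per_allele=round(float(o), 4))
        for i, (p, o) in enumerate(zip(rafs, ors))
    ))


def _incidence_shape(age: int) -> float:
    """Unscaled log-linear hazard shape: 3e-5/yr at 35 rising to 3e-3/yr at 84."""
    k = np.log(100.0) / (84 - 35)
    return 3e-5 * float(np.exp(k * (age - 35)))


def synthetic_incidence_table(target_risk_age50: float = 0.009,
                              male_multiplier: float = 1.2,
                              female_multiplier: float = 0.8) -> IncidenceTable:
    """Synthetic age-sex incidence table anchored to scenario 2's 0.9% threshold.

    Rates rise log-linearly with age; male rates exceed female rates.
    The whole surface is scaled so the sex-averaged 10-year risk at age
    50 equals ``target_risk_age50`` exactly.
    """
    h50 = sum(_incidence_shape(t) for t in range(50, 60))

    def avg_risk_at_50(scale: float) -> float:
        risks = [1.0 - np.exp(-scale * m * h50)
                 for m in (male_multiplier, female_multiplier)]
        return float(np.mean(risks))

    scale = brentq(lambda s: avg_risk_at_50(s) - target_risk_age50, 1e-6, 1e3,
                   xtol=1e-15, rtol=1e-15)
    rates = {}
    for age in range(AGE_MIN, AGE_MAX + 10):
        base = scale * _incidence_shape(age)
        rates[(age, "male")] = base * male_multiplier
        rates[(age, "female")] = base * female_multiplier
    return IncidenceTable(rates)


def synthetic_projection_frame():
    """Synthetic population projection: persons per (age, sex), ages 35-74.

    A gently declining age profile normalised to a fixed total of
    12,221,045 persons; rounding residue is absorbed by the youngest
    male cell so the total is exact.
    """
    import pandas as pd

    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    weights = np.exp(-0.012 * (ages - AGE_MIN))
    cell_share = weights / (2.0 * weights.sum())  # per sex
    rows = []
    allocated = 0
    for sex in ("male", "female"):
        for a, s in zip(ages, cell_share):
            persons = int(np.floor(s * DEFAULT_POPULATION_TOTAL))
            rows.append({"age": int(a), "sex": sex, "persons": persons})
            allocated += persons
    rows[0]["persons"] += DEFAULT_POPULATION_TOTAL - allocated
    return pd.DataFrame(rows, columns=["age", "sex", "persons"])


def default_cohort_spec(seed: int = 0, n: int = DEFAULT_COHORT_N) -> CohortSpec:
    """The default synthetic-cohort recipe (uniform ages, balanced sexes)."""
    return CohortSpec(
        n=n,
        factors=default_factors(),
        fh_distribution=default_fh_distribution(),
        sex_ratio=0.5,
        age_weights=None,
        seed=seed,
    )
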