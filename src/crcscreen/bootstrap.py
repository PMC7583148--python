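"""Mixed nonparametric/parametric bootstrap over the cohort.

Each replicate resamples people with replacement (their lifestyle and
family-history RRs travel with them — the nonparametric part) and draws
a fresh polygenic RR for every sampled person from the panel's centered
distribution (the parametric part).  Combined RRs are re-calibrated to
the incidence table within the replicate, converted to 10-year absolute
risks, and every screening scenario is applied; the replicate yields the
share of people and of expected cancers per screening group.

Final estimates are medians across replicates with 95% intervals taken
as the 2.5th and 97.5th percentiles (linear-interpolation percentiles,
index = q*(n-1)).  Default scale: 500 replicates of 4000 people.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .absolute import (GROUPS, IncidenceTable, calibrate_baseline,
                       expected_cancer_shares, ten_year_risk_vec)
from .cohort import Person, cohort_arrays
from .risk import ModelComponents, SnpPanel, sample_genomic_rr
from .scenarios import ScenarioDefinition, assign_vec


class BootstrapError(ValueError):
    pass


@dataclass(frozen=True)
class BootstrapConfig:
    n_replicates: int = 500
    sample_size: int = 4000
    seed: int = 0
    genomic_method: str = "lognormal"  # 'lognormal' | 'exact'
    calibration_mode: str = "global"

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise BootstrapError("n_replicates must be >= 1")
        if self.sample_size < 1:
            raise BootstrapError("sample_size must be >= 1")


def percentile(values: Sequence[float], q: float) -> float:
    """Linear-interpolation percentile (index = q*(n-1)); q=0.5 is the median."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise BootstrapError("percentile of empty sequence")
    if not 0.0 <= q <= 1.0:
        raise BootstrapError(f"q must be in [0, 1], got {q}")
    return float(np.quantile(arr, q, method="linear"))


@dataclass(frozen=True)
class GroupSummary:
    """Bootstrap summary for one scenario x screening group.

    Share triples are (median, lo 2.5th, hi 97.5th).  Counts are the
    population-scaled equivalents, present once a projection is applied.
    """

    scenario_id: str
    group: str
    people_share: tuple[float, float, float]
    cancer_share: tuple[float, float, float]
    people_count: Optional[tuple[int, int, int]] = None
    cancer_count: Optional[tuple[int, int, int]] = None

    def __post_init__(self) -> None:
        for name in ("people_share", "cancer_share"):
            med, lo, hi = getattr(self, name)
            if not (lo <= med <= hi):
                raise BootstrapError(f"{name}: need lo <= median <= hi")
            if not (0.0 <= lo and hi <= 1.0):
                raise BootstrapError(f"{name}: shares must be in [0, 1]")


def run_replicate(cohort_cols: dict, panel: SnpPanel, incidence: IncidenceTable,
                  scenarios: Sequence[ScenarioDefinition],
                  components: ModelComponents, rng: np.random.Generator,
                  sample_size: int, genomic_method: str = "lognormal",
                  calibration_mode: str = "global") -> dict:
    """One bootstrap replicate; returns per-scenario shares and the mean risk.

    ``cohort_cols`` is the columnar cohort view from
    :func:`crcscreen.cohort.cohort_arrays` and must include the static
    ``rr_lifestyle`` and ``rr_family`` columns.
    """
    n = cohort_cols["age"].size
    if n == 0:
        raise BootstrapError("cohort is empty")
    for col in ("rr_lifestyle", "rr_family"):
        if col not in cohort_cols:
            raise BootstrapError(f"cohort is missing precomputed {col}")
    idx = rng.integers(0, n, size=sample_size)
    ages = cohort_cols["age"][idx]
    sex_codes = cohort_cols["sex_code"][idx]
    rr_life = cohort_cols["rr_lifestyle"][idx]
    rr_fam = cohort_cols["rr_family"][idx]
    if components.use_genomic:
        rr_gen = sample_genomic_rr(panel, sample_size, rng, method=genomic_method)
    else:
        rr_gen = np.ones(sample_size)

    rr = np.ones(sample_size)
    if components.use_lifestyle:
        rr = rr * rr_life
    if components.use_genomic:
        rr = rr * rr_gen
    if components.use_family_history:
        rr = rr * rr_fam

    sexes = np.array(["male", "female"])[sex_codes]
    baseline = calibrate_baseline(incidence, rr, ages=ages, sexes=sexes,
                                  mode=calibration_mode)
    risks = ten_year_risk_vec(ages, sex_codes, rr, baseline.cum_hazard_table())

    result: dict = {"mean_risk": float(risks.mean()), "scenarios": {}}
    for sc in scenarios:
        if sc.kind == "threshold_absolute":
            values = risks
        elif sc.rr_source == "family_history":
            values = rr_fam
        else:
            values = rr
        modalities, categories = assign_vec(sc, ages, sex_codes, values)
        shares = expected_cancer_shares(risks, modalities)
        cat_labels, cat_counts = np.unique(categories, return_counts=True)
        result["scenarios"][sc.id] = {
            "people": {g: shares[g][0] for g in GROUPS},
            "cancers": {g: shares[g][1] for g in GROUPS},
            "categories": {str(l): c / sample_size
                           for l, c in zip(cat_labels, cat_counts)},
        }
    return result


@dataclass
class BootstrapResult:
    """Raw per-replicate shares plus summarisation helpers."""

    config: BootstrapConfig
    scenario_ids: list[str]
    # arrays keyed (scenario_id, group) -> shape (n_replicates,)
    people_shares: dict = field(default_factory=dict)
    cancer_shares: dict = field(default_factory=dict)
    category_shares: dict = field(default_factory=dict)  # (scenario_id, label)
    mean_risks: np.ndarray = field(default_factory=lambda: np.empty(0))

    def summarize(self, population_total: Optional[int] = None) -> list[GroupSummary]:
        """Median and 2.5/97.5 percentile summaries per scenario x group.

        When ``population_total`` is given, counts are scaled per
        replicate (people: share x total; cancers: cancer share x mean
        replicate risk x total) and summarised on the count scale.
        """
        out = []
        for sid in self.scenario_ids:
            for g in GROUPS:
                ps = self.people_shares[(sid, g)]
                cs = self.cancer_shares[(sid, g)]
                people_count = cancer_count = None
                if population_total is not None:
                    pc = ps * population_total
                    cc = cs * self.mean_risks * population_total
                    people_count = tuple(int(round(percentile(pc, q)))
                                         for q in (0.5, 0.025, 0.975))
                    cancer_count = tuple(int(round(percentile(cc, q)))
                                         for q in (0.5, 0.025, 0.975))
                out.append(GroupSummary(
                    scenario_id=sid, group=g,
                    people_share=tuple(percentile(ps, q) for q in (0.5, 0.025, 0.975)),
                    cancer_share=tuple(percentile(cs, q) for q in (0.5, 0.025, 0.975)),
                    people_count=people_count, cancer_count=cancer_count,
                ))
        return out

    def category_summary(self, scenario_id: str) -> dict[str, tuple[float, float, float]]:
        """Median (and 95% interval) people share per risk category."""
        out = {}
        for (sid, label), arr in sorted(self.category_shares.items()):
            if sid == scenario_id:
                out[label] = tuple(percentile(arr, q) for q in (0.5, 0.025, 0.975))
        return out


def run_bootstrap(config: BootstrapConfig, cohort: Sequence[Person],
                  panel: SnpPanel, incidence: IncidenceTable,
                  scenarios: Sequence[ScenarioDefinition],
                  components: ModelComponents = ModelComponents()
                  ) -> BootstrapResult:
    """Run the full bootstrap; fully deterministic given ``config.seed``.

    Per-replicate generators are spawned from a single seed sequence, so
    replicates are independent and the whole run is reproducible from
    the one master seed.
    """
    cols = cohort_arrays(cohort)
    if "rr_lifestyle" not in cols or "rr_family" not in cols:
        raise BootstrapError(
            "cohort must have rr_lifestyle and rr_family set on every person "
            "(see risk.attach_static_rrs)"
        )
    n_rep = config.n_replicates
    scenario_ids = [sc.id for sc in scenarios]
    res = BootstrapResult(config=config, scenario_ids=scenario_ids)
    res.people_shares = {(sid, g): np.empty(n_rep) for sid in scenario_ids
                         for g in GROUPS}
    res.cancer_shares = {(sid, g): np.empty(n_rep) for sid in scenario_ids
                         for g in GROUPS}
    res.mean_risks = np.empty(n_rep)
    cat_acc: dict = {}

    children = np.random.SeedSequence(config.seed).spawn(n_rep)
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        rep = run_replicate(cols, panel, incidence, scenarios, components, rng,
                            config.sample_size, config.genomic_method,
                            config.calibration_mode)
        res.mean_risks[r] = rep["mean_risk"]
        for sid in scenario_ids:
            for g in GROUPS:
                res.people_shares[(sid, g)][r] = rep["scenarios"][sid]["people"][g]
                res.cancer_shares[(sid, g)][r] = rep["scenarios"][sid]["cancers"][g]
            for label, share in rep["scenarios"][sid]["categories"].items():
                cat_acc.setdefault((sid, label), np.zeros(n_rep))[r] = share
    res.category_shares = cat_acc
    return res
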