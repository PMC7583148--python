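"""Single-file YAML/JSON configuration for the whole pipeline.

Every input table has a packaged synthetic default (see
:mod:`crcscreen.defaults`); a config file only needs to name what it
overrides.  Recognised top-level keys: ``cohort``, ``factors``,
``family_history``, ``snp_panel``, ``incidence``, ``projection``,
``scenarios``, ``bootstrap``, ``components``, ``sensitivities``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import defaults
from .absolute import IncidenceTable
from .bootstrap import BootstrapConfig
from .cohort import (CohortSpec, FamilyHistoryConstellation,
                     RiskFactorDefinition)
from .reporting import ModalitySensitivity, PopulationProjection
from .risk import (FamilyHistoryRule, FamilyHistoryTable, ModelComponents,
                   SnpPanel)
from .scenarios import (AgeRule, ScenarioDefinition, default_scenarios,
                        scenario_s2)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Fully resolved inputs for one pipeline run."""

    cohort_spec: CohortSpec
    factors: list[RiskFactorDefinition]
    fh_table: FamilyHistoryTable
    fh_distribution: list[tuple[FamilyHistoryConstellation, float]]
    panel: SnpPanel
    incidence: IncidenceTable
    projection: PopulationProjection
    scenarios: list[ScenarioDefinition]
    bootstrap: BootstrapConfig
    components: ModelComponents = field(default_factory=ModelComponents)
    sensitivities: ModalitySensitivity = field(default_factory=ModalitySensitivity)


def _parse_factors(items) -> list[RiskFactorDefinition]:
    out = []
    for d in items:
        try:
            out.append(RiskFactorDefinition(
                name=d["name"], levels=tuple(d["levels"]),
                prevalences=tuple(float(p) for p in d["prevalences"]),
                rrs=tuple(float(r) for r in d["rrs"])))
        except KeyError as e:
            raise ConfigError(f"factor definition missing key {e}") from None
    return out


def _parse_family_history(d):
    rules = tuple(
        FamilyHistoryRule(rr=float(r["rr"]), min_fdr=int(r.get("min_fdr", 0)),
                          min_sdr=int(r.get("min_sdr", 0)),
                          dx_before=(int(r["dx_before"]) if "dx_before" in r
                                     and r["dx_before"] is not None else None))
        for r in d.get("rules", ()))
    table = FamilyHistoryTable(rules=rules,
                               default_rr=float(d.get("default_rr", 1.0)))
    dist = []
    for item in d.get("distribution", ()):
        dx = item.get("youngest_dx_age")
        dist.append((FamilyHistoryConstellation(
            n_fdr=int(item.get("n_fdr", 0)), n_sdr=int(item.get("n_sdr", 0)),
            youngest_dx_age=(int(dx) if dx is not None else None)),
            float(item["prob"])))
    return table, dist


def _parse_age_rules(d) -> dict[str, tuple[AgeRule, ...]]:
    out = {}
    for cat, rules in d.items():
        out[str(cat)] = tuple(
            AgeRule(age_lo=int(r["age_lo"]), age_hi=int(r["age_hi"]),
                    modality=r["modality"],
                    interval_years=(int(r["interval_years"])
                                    if r.get("interval_years") is not None else None))
            for r in rules)
    return out


def _parse_bounds(bounds) -> tuple[tuple[str, float], ...]:
    parsed = []
    for label, upper in bounds:
        parsed.append((str(label),
                       math.inf if upper in (None, "inf", ".inf") else float(upper)))
    return tuple(parsed)


def _parse_scenario(d) -> ScenarioDefinition:
    if isinstance(d, str):
        by_id = {sc.id: sc for sc in default_scenarios()}
        if d not in by_id:
            raise ConfigError(f"unknown scenario id {d!r}; packaged: {sorted(by_id)}")
        return by_id[d]
    kind = d.get("kind", "category_rr")
    if kind == "threshold_absolute":
        t = d.get("abs_thresholds", [0.009, 0.040])
        return scenario_s2(float(t[0]), float(t[1]), id=d["id"])
    raw_bounds = d.get("category_bounds", {})
    bounds = {}
    for sex, b in raw_bounds.items():
        key = None if sex in (None, "both", "all") else str(sex)
        bounds[key] = _parse_bounds(b)
    from .scenarios import default_age_rules
    rules = (_parse_age_rules(d["age_rules"]) if "age_rules" in d
             else default_age_rules())
    return ScenarioDefinition(id=d["id"], kind="category_rr",
                              rr_source=d.get("rr_source", "combined"),
                              category_bounds=bounds, age_rules=rules)


def config_from_dict(raw: Optional[dict] = None,
                     base_dir: Optional[Path] = None) -> RunConfig:
    """Resolve a (possibly partial) config mapping against packaged defaults."""
    raw = dict(raw or {})
    base = Path(base_dir) if base_dir else Path(".")

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    factors = (_parse_factors(raw["factors"]) if "factors" in raw
               else defaults.default_factors())
    if "family_history" in raw:
        fh_table, fh_dist = _parse_family_history(raw["family_history"])
        if not fh_dist:
            fh_dist = defaults.default_fh_distribution()
    else:
        fh_table = defaults.default_family_history_table()
        fh_dist = defaults.default_fh_distribution()

    cohort_raw = raw.get("cohort", {})
    cohort_spec = CohortSpec(
        n=int(cohort_raw.get("n", defaults.DEFAULT_COHORT_N)),
        factors=factors, fh_distribution=fh_dist,
        sex_ratio=float(cohort_raw.get("sex_ratio", 0.5)),
        age_weights=({int(k): float(v) for k, v in cohort_raw["age_weights"].items()}
                     if "age_weights" in cohort_raw else None),
        seed=int(cohort_raw.get("seed", 0)))

    panel = (SnpPanel.from_tsv(resolve(raw["snp_panel"])) if "snp_panel" in raw
             else defaults.default_snp_panel())
    incidence = (IncidenceTable.from_csv(resolve(raw["incidence"]))
                 if "incidence" in raw else defaults.synthetic_incidence_table())
    projection = (PopulationProjection.from_csv(resolve(raw["projection"]))
                  if "projection" in raw
                  else PopulationProjection.from_frame(
                      defaults.synthetic_projection_frame()))

    scenarios = ([_parse_scenario(s) for s in raw["scenarios"]]
                 if "scenarios" in raw else default_scenarios())

    b = raw.get("bootstrap", {})
    bootstrap = BootstrapConfig(
        n_replicates=int(b.get("n_replicates", 500)),
        sample_size=int(b.get("sample_size", 4000)),
        seed=int(b.get("seed", 0)),
        genomic_method=str(b.get("genomic_method", "lognormal")),
        calibration_mode=str(b.get("calibration_mode", "global")))

    c = raw.get("components", {})
    components = ModelComponents(
        use_lifestyle=bool(c.get("use_lifestyle", True)),
        use_genomic=bool(c.get("use_genomic", True)),
        use_family_history=bool(c.get("use_family_history", True)))

    s = raw.get("sensitivities", {})
    sensitivities = ModalitySensitivity(
        colonoscopy=float(s.get("colonoscopy", 0.95)),
        ifobt=float(s.get("ifobt", 0.83)))

    return RunConfig(cohort_spec=cohort_spec, factors=factors, fh_table=fh_table,
                     fh_distribution=fh_dist, panel=panel, incidence=incidence,
                     projection=projection, scenarios=scenarios,
                     bootstrap=bootstrap, components=components,
                     sensitivities=sensitivities)


def load_config(path) -> RunConfig:
    """Load a YAML or JSON config file; missing keys fall back to defaults."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    text = p.read_text()
    raw = (json.loads(text) if p.suffix == ".json" else yaml.safe_load(text)) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return config_from_dict(raw, base_dir=p.parent)


def config_digest(raw: Optional[dict]) -> str:
    """Short stable digest of the raw config mapping, for run provenance logs."""
    canon = json.dumps(raw or {}, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
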