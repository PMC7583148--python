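"""Population scaling, scenario comparison and summary rendering."""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .absolute import GROUPS
from .bootstrap import GroupSummary
from .cohort import AGE_MAX, AGE_MIN, SEXES


class ReportingError(ValueError):
    pass


@dataclass(frozen=True)
class PopulationProjection:
    """Projected persons per (age, sex) stratum covering ages 35-74."""

    persons: Mapping[tuple[int, str], int]

    def __post_init__(self) -> None:
        for age in range(AGE_MIN, AGE_MAX + 1):
            for sex in SEXES:
                if (age, sex) not in self.persons:
                    raise ReportingError(f"projection missing (age={age}, sex={sex})")
                if self.persons[(age, sex)] < 0:
                    raise ReportingError(f"negative persons at (age={age}, sex={sex})")

    @property
    def total_35_74(self) -> int:
        return int(sum(self.persons[(a, s)] for a in range(AGE_MIN, AGE_MAX + 1)
                       for s in SEXES))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PopulationProjection":
        for col in ("age", "sex", "persons"):
            if col not in df.columns:
                raise ReportingError(f"projection table missing column {col!r}")
        return cls({(int(r.age), str(r.sex)): int(r.persons)
                    for r in df.itertuples(index=False)})

    @classmethod
    def from_csv(cls, path) -> "PopulationProjection":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class ModalitySensitivity:
    """Per-modality sensitivity for CRC: colonoscopy ~95%, iFOBT ~83%."""

    colonoscopy: float = 0.95
    ifobt: float = 0.83

    def __post_init__(self) -> None:
        for name in ("colonoscopy", "ifobt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ReportingError(f"{name} sensitivity must be in [0, 1]")


def scale_to_population(share: float, projection: PopulationProjection) -> int:
    """Convert a population share into persons, rounded to nearest integer."""
    if not 0.0 <= share <= 1.0:
        raise ReportingError(f"share must be in [0, 1], got {share}")
    return int(round(share * projection.total_35_74))


def screen_detectable(cancer_shares: Mapping[str, float],
                      sens: ModalitySensitivity = ModalitySensitivity()) -> float:
    """Proportion of expected cancers detectable by the recommended modality.

    Weights each screened group's cancer share by that modality's
    sensitivity; the unscreened group contributes nothing.
    """
    total = sum(cancer_shares.get(g, 0.0) for g in GROUPS)
    if abs(total - 1.0) > 1e-9:
        raise ReportingError(f"cancer shares sum to {total}, not 1")
    return (sens.colonoscopy * cancer_shares.get("colonoscopy", 0.0)
            + sens.ifobt * cancer_shares.get("iFOBT", 0.0))


def percent_change(a: float, b: float) -> Optional[int]:
    """Integer-rounded percent change 100*(b-a)/a; None when a is zero."""
    if a == 0:
        return None
    return int(round(100.0 * (b - a) / a))


def compare_scenarios(a: Sequence[GroupSummary],
                      b: Sequence[GroupSummary]) -> pd.DataFrame:
    """Per-group differences between two scenarios' population-scaled medians.

    Returns one row per screening group with absolute differences and
    integer-rounded percent changes of people and cancer counts;
    division by zero is reported as missing (rendered "undefined"), not
    infinity.
    """
    a_by = {s.group: s for s in a}
    b_by = {s.group: s for s in b}
    if set(a_by) != set(b_by):
        raise ReportingError("scenario summaries have mismatched groups")
    rows = []
    for g in GROUPS:
        sa, sb = a_by[g], b_by[g]
        if sa.people_count is None or sb.people_count is None:
            raise ReportingError("summaries must be population-scaled before comparison")
        pa, pb = sa.people_count[0], sb.people_count[0]
        ca, cb = sa.cancer_count[0], sb.cancer_count[0]
        rows.append({
            "group": g,
            "people_a": pa, "people_b": pb, "people_diff": pb - pa,
            "people_pct_change": percent_change(pa, pb),
            "cancers_a": ca, "cancers_b": cb, "cancers_diff": cb - ca,
            "cancers_pct_change": percent_change(ca, cb),
        })
    return pd.DataFrame(rows)


def summaries_to_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "scenario": s.scenario_id, "group": s.group,
            "people_share": s.people_share[0],
            "people_share_lo": s.people_share[1], "people_share_hi": s.people_share[2],
            "cancer_share": s.cancer_share[0],
            "cancer_share_lo": s.cancer_share[1], "cancer_share_hi": s.cancer_share[2],
        }
        if s.people_count is not None:
            row.update(people_count=s.people_count[0],
                       people_count_lo=s.people_count[1],
                       people_count_hi=s.people_count[2])
        if s.cancer_count is not None:
            row.update(cancer_count=s.cancer_count[0],
                       cancer_count_lo=s.cancer_count[1],
                       cancer_count_hi=s.cancer_count[2])
        rows.append(row)
    return pd.DataFrame(rows)


def summaries_to_json_dict(summaries: Sequence[GroupSummary]) -> dict:
    out: dict = {}
    for s in summaries:
        entry = {
            "people_share": list(s.people_share),
            "cancer_share": list(s.cancer_share),
        }
        if s.people_count is not None:
            entry["people_count"] = list(s.people_count)
        if s.cancer_count is not None:
            entry["cancer_count"] = list(s.cancer_count)
        out.setdefault(s.scenario_id, {})[s.group] = entry
    return out


def summaries_from_json_dict(data: Mapping) -> list[GroupSummary]:
    out = []
    for sid in sorted(data):
        for g in GROUPS:
            if g not in data[sid]:
                continue
            e = data[sid][g]
            out.append(GroupSummary(
                scenario_id=sid, group=g,
                people_share=tuple(e["people_share"]),
                cancer_share=tuple(e["cancer_share"]),
                people_count=(tuple(e["people_count"])
                              if "people_count" in e else None),
                cancer_count=(tuple(e["cancer_count"])
                              if "cancer_count" in e else None),
            ))
    return out


def _fmt_pct(x: float) -> str:
    return f"{100.0 * x:.1f}%"


def render_summary(summaries: Sequence[GroupSummary], fmt: str = "text",
                   stream=None) -> str:
    """Render summaries as text table, CSV or JSON (bit-stable given inputs).

    Shares are rendered to 0.1 percentage point and counts to integers,
    so rendered shares within a scenario may not sum to exactly 100%.
    """
    if fmt == "json":
        rendered = json.dumps(summaries_to_json_dict(summaries), indent=2,
                              sort_keys=True) + "\n"
    elif fmt == "csv":
        buf = io.StringIO()
        summaries_to_frame(summaries).to_csv(buf, index=False, lineterminator="\n")
        rendered = buf.getvalue()
    elif fmt == "text":
        lines = [f"{'scenario':<8} {'group':<12} {'people %':>10} "
                 f"{'people 95% CI':>18} {'cancers %':>10} {'cancers 95% CI':>18} "
                 f"{'people N':>12} {'cancers N':>10}"]
        for s in summaries:
            pc = f"{s.people_count[0]:,}" if s.people_count else "-"
            cc = f"{s.cancer_count[0]:,}" if s.cancer_count else "-"
            lines.append(
                f"{s.scenario_id:<8} {s.group:<12} {_fmt_pct(s.people_share[0]):>10} "
                f"[{_fmt_pct(s.people_share[1])}, {_fmt_pct(s.people_share[2])}]"
                f"{'':>1} {_fmt_pct(s.cancer_share[0]):>10} "
                f"[{_fmt_pct(s.cancer_share[1])}, {_fmt_pct(s.cancer_share[2])}]"
                f"{'':>1} {pc:>12} {cc:>10}")
        if summaries:
            lines.append("note: rendered shares may not sum to 100% due to rounding")
        rendered = "\n".join(lines) + "\n"
    else:
        raise ReportingError(f"unknown format {fmt!r}; use text, csv or json")
    if stream is not None:
        stream.write(rendered)
    return rendered
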