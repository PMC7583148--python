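"""End-to-end orchestration: cohort -> risks -> bootstrap -> summaries."""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .bootstrap import BootstrapResult, GroupSummary, run_bootstrap
from .cohort import Person, generate_cohort
from .config import RunConfig
from .risk import attach_static_rrs

log = logging.getLogger("crcscreen")


def prepare_cohort(cfg: RunConfig, cohort: Optional[Sequence[Person]] = None
                   ) -> list[Person]:
    """Generate (or take) the cohort and attach its static RR components."""
    people = list(cohort) if cohort is not None else generate_cohort(cfg.cohort_spec)
    attach_static_rrs(people, cfg.factors, cfg.fh_table)
    return people


def run_pipeline(cfg: RunConfig, cohort: Optional[Sequence[Person]] = None
                 ) -> tuple[BootstrapResult, list[GroupSummary]]:
    """Run the full bootstrap and return raw results plus scaled summaries."""
    people = prepare_cohort(cfg, cohort)
    log.info("cohort ready: n=%d persons; bootstrap seed=%d, %d replicates x %d",
             len(people), cfg.bootstrap.seed, cfg.bootstrap.n_replicates,
             cfg.bootstrap.sample_size)
    result = run_bootstrap(cfg.bootstrap, people, cfg.panel, cfg.incidence,
                           cfg.scenarios, cfg.components)
    summaries = result.summarize(population_total=cfg.projection.total_35_74)
    return result, summaries
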