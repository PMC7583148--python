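"""Relative-risk engine: lifestyle, family-history and polygenic components.

Each person's CRC relative risk is the product (log-additive sum) of up
to three components:

* a lifestyle RR from categorical risk factors, normalised so the
  population-mean lifestyle RR is 1 under the configured prevalences;
* a family-history RR from a first-match rule table keyed on the number,
  degree and age at diagnosis of affected relatives (referent 1.0);
* a polygenic RR from a SNP panel under Hardy-Weinberg equilibrium,
  centered per SNP so the population-mean genomic RR is exactly 1.

No interaction terms are modelled: the three components multiply.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import FamilyHistoryConstellation, Person, RiskFactorDefinition


class RiskModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# SNP panel and the polygenic RR distribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Snp:
    id: str
    raf: float           # risk-allele frequency
    or_per_allele: float

    def __post_init__(self) -> None:
        if not 0.0 < self.raf < 1.0:
            raise RiskModelError(f"SNP {self.id!r}: raf must be in (0,1), got {self.raf}")
        if self.or_per_allele <= 0:
            raise RiskModelError(f"SNP {self.id!r}: odds ratio must be > 0")


@dataclass(frozen=True)
class SnpPanel:
    snps: tuple[Snp, ...]

    def __post_init__(self) -> None:
        if not self.snps:
            raise RiskModelError("SNP panel is empty")
        ids = [s.id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise RiskModelError("SNP panel has duplicate ids")

    def __len__(self) -> int:
        return len(self.snps)

    @classmethod
    def from_tsv(cls, path) -> "SnpPanel":
        """Read a panel from TSV with columns id, raf, or_per_allele."""
        df = pd.read_csv(path, sep="\t")
        for col in ("id", "raf", "or_per_allele"):
            if col not in df.columns:
                raise RiskModelError(f"SNP panel file missing column {col!r}")
        return cls(tuple(Snp(str(r.id), float(r.raf), float(r.or_per_allele))
                         for r in df.itertuples(index=False)))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"id": [s.id for s in self.snps],
             "raf": [s.raf for s in self.snps],
             "or_per_allele": [s.or_per_allele for s in self.snps]}
        ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def hwe_genotype_probs(raf: float) -> np.ndarray:
    """Hardy-Weinberg probabilities of carrying 0, 1 or 2 risk alleles."""
    q = 1.0 - raf
    return np.array([q * q, 2.0 * raf * q, raf * raf])


def centered_snp_rrs(snp: Snp) -> tuple[np.ndarray, np.ndarray]:
    """Per-genotype centered RRs for one SNP and their HWE probabilities.

    The raw per-genotype RR is OR**g; dividing by the population mean
    E[OR**g] makes the expected RR exactly 1.
    """
    probs = hwe_genotype_probs(snp.raf)
    raw = snp.or_per_allele ** np.arange(3)
    return raw / float(probs @ raw), probs


@dataclass(frozen=True)
class GenomicDistribution:
    """Lognormal summary of the centered polygenic log-RR distribution.

    ``sigma2`` is the variance of the log-RR summed over independent SNPs;
    when ``centered`` the location is mu = -sigma2/2 so that the lognormal
    mean RR is exp(mu + sigma2/2) = 1.
    """

    mu: float
    sigma2: float
    centered: bool = True

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise RiskModelError("sigma2 must be >= 0")
        if self.centered and abs(self.mu - (-self.sigma2 / 2.0)) > 1e-12:
            raise RiskModelError("centered distribution requires mu = -sigma2/2")


def genomic_distribution(panel: SnpPanel) -> GenomicDistribution:
    """Lognormal approximation of the panel's centered RR distribution.

    Per SNP the genotype g is Binomial(2, raf) under HWE, contributing
    g*log(OR) to the log-RR with variance 2*raf*(1-raf)*log(OR)^2;
    variances add across independent SNPs.
    """
    sigma2 = 0.0
    for s in panel.snps:
        sigma2 += 2.0 * s.raf * (1.0 - s.raf) * np.log(s.or_per_allele) ** 2
    return GenomicDistribution(mu=-sigma2 / 2.0, sigma2=sigma2, centered=True)


def sample_genomic_rr(panel: SnpPanel, n: int,
                      seed: Union[int, np.random.Generator, None] = None,
                      method: str = "exact") -> np.ndarray:
    """Draw ``n`` polygenic RRs from the panel's centered distribution.

    ``exact`` draws genotypes per SNP under HWE and exponentiates the
    centered log-RR sum; ``lognormal`` draws from the Normal(mu, sigma2)
    approximation on the log scale.  Both have population-mean RR 1 in
    expectation.
    """
    if n <= 0:
        raise RiskModelError(f"n must be > 0, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if method == "exact":
        log_rr = np.zeros(n)
        for s in panel.snps:
            if s.or_per_allele == 1.0:
                continue  # null SNP contributes exactly 1
            g = rng.binomial(2, s.raf, size=n)
            probs = hwe_genotype_probs(s.raf)
            raw = s.or_per_allele ** np.arange(3)
            log_rr += g * np.log(s.or_per_allele) - np.log(float(probs @ raw))
        return np.exp(log_rr)
    if method == "lognormal":
        dist = genomic_distribution(panel)
        return np.exp(rng.normal(dist.mu, np.sqrt(dist.sigma2), size=n))
    raise RiskModelError(f"unknown sampling method {method!r}; use 'exact' or 'lognormal'")


def enumerate_genomic_rrs(panel: SnpPanel) -> tuple[np.ndarray, np.ndarray]:
    """Exact centered RR support and probabilities over all 3^k genotype combos.

    Brute-force enumeration; intended for small panels (k <= ~10).
    """
    rrs = np.array([1.0])
    probs = np.array([1.0])
    for s in panel.snps:
        snp_rr, snp_p = centered_snp_rrs(s)
        rrs = np.outer(rrs, snp_rr).ravel()
        probs = np.outer(probs, snp_p).ravel()
    return rrs, probs


# ---------------------------------------------------------------------------
# Lifestyle component
# ---------------------------------------------------------------------------

def lifestyle_rr(person: Person, factors: Sequence[RiskFactorDefinition]) -> float:
    """Normalised lifestyle RR: product over factors of RR(level) / mean RR.

    Dividing each factor's level RR by its population-mean RR
    (sum of prevalence x RR) makes the population-mean lifestyle RR 1
    under the configured prevalences.
    """
    rr = 1.0
    for f in factors:
        if f.name not in person.factor_levels:
            raise RiskModelError(
                f"person {person.id!r} is missing configured factor {f.name!r}"
            )
        level = person.factor_levels[f.name]
        try:
            i = f.levels.index(level)
        except ValueError:
            raise RiskModelError(
                f"person {person.id!r}: unknown level {level!r} for factor {f.name!r}"
            ) from None
        rr *= f.rrs[i] / f.mean_rr()
    return rr


# ---------------------------------------------------------------------------
# Family-history component
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyHistoryRule:
    """One row of the family-history RR table; first matching rule wins.

    A constellation matches when it has at least ``min_fdr`` affected
    first-degree and ``min_sdr`` second-degree relatives and, when
    ``dx_before`` is set, the youngest diagnosis was before that age.
    """

    rr: float
    min_fdr: int = 0
    min_sdr: int = 0
    dx_before: Optional[int] = None

    def __post_init__(self) -> None:
        if self.rr <= 0:
            raise RiskModelError("rule RR must be > 0")

    def matches(self, fh: FamilyHistoryConstellation) -> bool:
        if fh.n_fdr < self.min_fdr or fh.n_sdr < self.min_sdr:
            return False
        if self.dx_before is not None:
            if fh.youngest_dx_age is None or fh.youngest_dx_age >= self.dx_before:
                return False
        return True


@dataclass(frozen=True)
class FamilyHistoryTable:
    rules: tuple[FamilyHistoryRule, ...]
    default_rr: float = 1.0

    def __post_init__(self) -> None:
        if self.default_rr <= 0:
            raise RiskModelError("default_rr must be > 0")

    def rr_for(self, fh: FamilyHistoryConstellation) -> float:
        for rule in self.rules:
            if rule.matches(fh):
                return rule.rr
        return self.default_rr

    def mean_rr(self, fh_distribution) -> float:
        """Analytic mean family-history RR under a constellation distribution."""
        return float(sum(p * self.rr_for(c) for c, p in fh_distribution))


def family_history_rr(person: Person, table: FamilyHistoryTable) -> float:
    """RR of the first matching rule; no family history falls to the default (1.0)."""
    return table.rr_for(person.family_history)


# ---------------------------------------------------------------------------
# Combination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelComponents:
    use_lifestyle: bool = True
    use_genomic: bool = True
    use_family_history: bool = True

    def __post_init__(self) -> None:
        if not (self.use_lifestyle or self.use_genomic or self.use_family_history):
            raise RiskModelError("at least one model component must be enabled")


def combine_rr(rr_lifestyle, rr_genomic, rr_family,
               components: ModelComponents = ModelComponents()):
    """Combine component RRs on a log-additive scale (product of enabled RRs).

    Disabled components contribute a factor of 1.  Accepts scalars or
    numpy arrays.
    """
    for name, v in (("lifestyle", rr_lifestyle), ("genomic", rr_genomic),
                    ("family", rr_family)):
        if np.any(np.asarray(v) <= 0):
            raise RiskModelError(f"rr_{name} must be > 0")
    out = np.asarray(1.0)
    if components.use_lifestyle:
        out = out * np.asarray(rr_lifestyle)
    if components.use_genomic:
        out = out * np.asarray(rr_genomic)
    if components.use_family_history:
        out = out * np.asarray(rr_family)
    return float(out) if out.ndim == 0 else out


def attach_static_rrs(cohort: Sequence[Person],
                      factors: Sequence[RiskFactorDefinition],
                      fh_table: FamilyHistoryTable) -> None:
    """Compute and set rr_lifestyle and rr_family on every person in place."""
    for p in cohort:
        p.rr_lifestyle = lifestyle_rr(p, factors)
        p.rr_family = family_history_rr(p, fh_table)
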