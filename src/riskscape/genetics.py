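"""Genotype quality checks and genetic risk grouping.

Covers three pieces of the genetic side of the analysis:

* a Hardy-Weinberg equilibrium chi-square (df = 1) for biallelic SNPs,
  with an optional exact test;
* APOE stratification into epsilon4 carriers / non-carriers, with
  epsilon2/epsilon4 heterozygotes flagged for exclusion (the two alleles
  have opposing effects, so carriers of both are removed);
* a three-SNP Alzheimer's-disease genetic risk score (AD-GRS) over
  CLU rs11136000, CR1 rs6656401 and PICALM rs3851179, using dominant
  (carrier) coding per SNP and a fixed low (0-1) / high (2-3) split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

__all__ = [
    "GenotypeCounts",
    "GeneticProfile",
    "ApoeGroup",
    "AdgrsGroup",
    "GeneticGroups",
    "hardy_weinberg_chisq",
    "hardy_weinberg_exact",
    "classify_apoe",
    "compute_adgrs",
    "classify_cohort_genetics",
    "RISK_ALLELES",
]

#: risk allele per AD-GRS SNP (carrier of the allele scores 1)
RISK_ALLELES = {"clu": "C", "cr1": "A", "picalm": "T"}

_VALID_APOE = {"e2", "e3", "e4"}


class ApoeGroup(str, Enum):
    E4_MINUS = "e4_minus"
    E4_PLUS = "e4_plus"
    EXCLUDED_E2E4 = "excluded_e2e4"


class AdgrsGroup(str, Enum):
    LOW = "low"
    HIGH = "high"


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed genotype counts for one biallelic SNP."""

    hom_ref: int
    het: int
    hom_alt: int

    def __post_init__(self) -> None:
        if min(self.hom_ref, self.het, self.hom_alt) < 0:
            raise ValueError("genotype counts must be non-negative")
        if self.total == 0:
            raise ValueError("total genotype count must be positive")

    @property
    def total(self) -> int:
        return self.hom_ref + self.het + self.hom_alt


@dataclass(frozen=True)
class GeneticProfile:
    """One participant's APOE allele pair and three AD-GRS genotype calls.

    APOE alleles are ``"e2"``/``"e3"``/``"e4"`` tokens; SNP calls are
    strings like ``"C/T"`` (case- and order-insensitive). Missing SNP
    calls may be ``None``.
    """

    apoe: str
    clu: str | None
    cr1: str | None
    picalm: str | None


@dataclass(frozen=True)
class GeneticGroups:
    apoe_group: ApoeGroup
    adgrs_score: int | None
    adgrs_group: AdgrsGroup | None


def _parse_alleles(call: str, snp: str) -> tuple[str, str]:
    parts = call.strip().upper().replace("|", "/").split("/")
    if len(parts) != 2 or not all(p in {"A", "C", "G", "T"} for p in parts):
        raise ValueError(f"unparseable genotype call {call!r} for {snp}")
    return parts[0], parts[1]


def _parse_apoe(call: str) -> tuple[str, str]:
    norm = call.strip().lower().replace("ε", "e").replace("|", "/")
    parts = norm.split("/")
    if len(parts) != 2 or not all(p in _VALID_APOE for p in parts):
        raise ValueError(f"unknown APOE allele pair {call!r}")
    return parts[0], parts[1]


def hardy_weinberg_chisq(counts: GenotypeCounts) -> tuple[float, int, float]:
    """Asymptotic Hardy-Weinberg chi-square test for one biallelic SNP.

    Allele frequencies are taken from the observed counts, expected
    genotype counts are n*p^2, 2npq, n*q^2 and the statistic is
    sum (O - E)^2 / E on 1 degree of freedom. No continuity correction.

    Returns ``(chi2, df, p)``.
    """
    n = counts.total
    q = (2 * counts.hom_alt + counts.het) / (2 * n)  # alt-allele frequency
    p = 1.0 - q
    if p == 0.0 or q == 0.0:
        raise ValueError("monomorphic SNP: Hardy-Weinberg statistic undefined")
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([counts.hom_ref, counts.het, counts.hom_alt], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return chi2, 1, float(stats.chi2.sf(chi2, df=1))


def hardy_weinberg_exact(counts: GenotypeCounts) -> float:
    """Exact Hardy-Weinberg test (Wigginton et al. 2005), two-sided p.

    Conditions on the observed allele counts and sums the probabilities
    of all heterozygote counts no more probable than the observed one.
    """
    n_alt = 2 * counts.hom_alt + counts.het
    n_ref = 2 * counts.hom_ref + counts.het
    if n_alt == 0 or n_ref == 0:
        raise ValueError("monomorphic SNP: exact test undefined")
    rare = min(n_alt, n_ref)
    n = counts.total
    # log-probability of each feasible heterozygote count under HWE
    hets = [h for h in range(rare % 2, rare + 1, 2)]
    logps = []
    for h in hets:
        a = (rare - h) // 2  # rare homozygotes
        b = n - a - h  # common homozygotes
        lp = (
            math.lgamma(n + 1)
            - math.lgamma(a + 1)
            - math.lgamma(h + 1)
            - math.lgamma(b + 1)
            + h * math.log(2.0)
            + math.lgamma(rare + 1)
            + math.lgamma(2 * n - rare + 1)
            - math.lgamma(2 * n + 1)
        )
        logps.append(lp)
    probs = np.exp(np.array(logps) - max(logps))
    probs /= probs.sum()
    obs_het = counts.het
    p_obs = probs[hets.index(obs_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def classify_apoe(profile: GeneticProfile | str) -> ApoeGroup:
    """Group an APOE allele pair into e4-, e4+, or the e2/e4 exclusion."""
    call = profile.apoe if isinstance(profile, GeneticProfile) else profile
    a, b = _parse_apoe(call)
    alleles = {a, b}
    if alleles == {"e2", "e4"}:
        return ApoeGroup.EXCLUDED_E2E4
    if "e4" in alleles:
        return ApoeGroup.E4_PLUS
    return ApoeGroup.E4_MINUS


def compute_adgrs(profile: GeneticProfile) -> tuple[int, AdgrsGroup]:
    """Carrier-coded three-SNP genetic risk score and low/high group.

    Each SNP contributes 1 if the participant carries at least one risk
    allele (CLU C, CR1 A, PICALM T), giving a 0-3 score; 0-1 is the low
    group, 2-3 the high group.
    """
    score = 0
    for snp in ("clu", "cr1", "picalm"):
        call = getattr(profile, snp)
        if call is None or (isinstance(call, float) and math.isnan(call)):
            raise ValueError(f"missing {snp} genotype: participant excluded "
                             "from genetic risk scoring")
        alleles = _parse_alleles(call, snp)
        score += int(RISK_ALLELES[snp] in alleles)
    group = AdgrsGroup.LOW if score <= 1 else AdgrsGroup.HIGH
    return score, group


def classify_cohort_genetics(profile: GeneticProfile) -> GeneticGroups:
    """APOE group plus AD-GRS for one participant; AD-GRS is None when
    any SNP call is missing (flagged out of genetic analyses)."""
    apoe_group = classify_apoe(profile)
    try:
        score, group = compute_adgrs(profile)
    except ValueError:
        score, group = None, None
    return GeneticGroups(apoe_group=apoe_group, adgrs_score=score, adgrs_group=group)
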