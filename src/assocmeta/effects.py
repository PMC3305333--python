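"""Per-study allelic effects, Hardy-Weinberg testing, and eligibility.

The allelic odds ratio contrasts the effect (minor) allele against the
other allele on the collapsed 2x2 allele table; genotype payloads are
collapsed to alleles first.  The standard error is Woolf's: the square
root of the sum of reciprocal cell counts.  A zero cell triggers a +0.5
continuity correction applied to all four cells (configurable off, in
which case zero-cell studies raise).

Hardy-Weinberg equilibrium in controls is tested either by the 1-df
chi-square goodness of fit or by the exact conditional test that
enumerates heterozygote counts given the allele count; departures at
P < 0.05 flag potential genotyping problems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Optional

import numpy as np
from scipy import stats

from .study_io import (AlleleCounts, GenotypeCounts, Payload, StudyCollection,
                       StudyRecord, SummaryEffect)

Z975 = 1.959964  # normal quantile at 0.975, used for all 95% intervals


class EstimationError(ValueError):
    """Effect not estimable from the given counts."""


@dataclass(frozen=True)
class StudyEffect:
    """One study's allelic log odds ratio with its bookkeeping.

    ``maf_controls``/``maf_pooled`` and ``minor_allele_count`` are NaN /
    0-filled for summary-only payloads, where counts are unavailable.
    """

    log_or: float
    se: float
    continuity_corrected: bool = False
    maf_controls: float = float("nan")
    maf_pooled: float = float("nan")
    minor_allele_count: int = 0
    hwe_p: Optional[float] = None
    n_cases: int = 0
    n_controls: int = 0

    @property
    def or_(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci95(self) -> tuple[float, float]:
        return (math.exp(self.log_or - Z975 * self.se),
                math.exp(self.log_or + Z975 * self.se))

    @property
    def variance(self) -> float:
        return self.se ** 2

    def flipped(self) -> "StudyEffect":
        """The same effect with minor/major labels swapped."""
        return replace(
            self, log_or=-self.log_or,
            maf_controls=1.0 - self.maf_controls,
            maf_pooled=1.0 - self.maf_pooled)


def study_odds_ratio(payload: Payload, *, continuity: bool = True,
                     n_cases: int = 0, n_controls: int = 0) -> StudyEffect:
    """Allelic odds ratio (effect allele vs. other) for one study.

    Parameters
    ----------
    payload
        Allele counts, genotype counts (collapsed to alleles), or a
        precomputed summary effect (passed through unchanged).
    continuity
        Add +0.5 to all four allele cells when any cell is zero.  With
        ``continuity=False`` a zero cell raises :class:`EstimationError`.
    """
    if isinstance(payload, SummaryEffect):
        return StudyEffect(log_or=payload.log_or, se=payload.se,
                           n_cases=n_cases, n_controls=n_controls)

    hwe_p: Optional[float] = None
    if isinstance(payload, GenotypeCounts):
        hwe_p = hwe_test(payload.controls).p
        counts = payload.to_allele_counts()
    else:
        counts = payload

    a, b = counts.case_minor, counts.case_major
    c, d = counts.ctrl_minor, counts.ctrl_major
    if a + b == 0 or c + d == 0:
        raise EstimationError("a group has zero total alleles")
    corrected = False
    if min(a, b, c, d) == 0:
        if not continuity:
            raise EstimationError(
                "zero cell with continuity correction disabled")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    n_cases = n_cases or round((counts.case_minor + counts.case_major) / 2)
    n_controls = n_controls or round(
        (counts.ctrl_minor + counts.ctrl_major) / 2)
    minor_total = counts.case_minor + counts.ctrl_minor
    total = (counts.case_minor + counts.case_major
             + counts.ctrl_minor + counts.ctrl_major)
    return StudyEffect(
        log_or=log_or, se=se, continuity_corrected=corrected,
        maf_controls=(counts.ctrl_minor / (counts.ctrl_minor + counts.ctrl_major)),
        maf_pooled=minor_total / total,
        minor_allele_count=minor_total,
        hwe_p=hwe_p, n_cases=n_cases, n_controls=n_controls)


def record_effect(record: StudyRecord, *, continuity: bool = True) -> StudyEffect:
    """Effect for a :class:`StudyRecord`, whatever its payload kind."""
    return study_odds_ratio(record.payload, continuity=continuity,
                            n_cases=record.n_cases,
                            n_controls=record.n_controls)


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------

class HweResult(NamedTuple):
    p: float
    method: str
    monomorphic: bool = False


def _hwe_chisq(hom_minor: int, het: int, hom_major: int) -> float:
    n = hom_minor + het + hom_major
    q = (2 * hom_minor + het) / (2 * n)  # minor allele frequency
    p = 1.0 - q
    expected = np.array([n * q * q, 2 * n * p * q, n * p * p])
    observed = np.array([hom_minor, het, hom_major], dtype=float)
    stat = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(stat, df=1))


def _hwe_exact(hom_minor: int, het: int, hom_major: int) -> float:
    # Conditional enumeration of heterozygote counts given the minor-allele
    # count; probabilities accumulated in log space for stability.
    from scipy.special import gammaln

    n = hom_minor + het + hom_major
    n_minor = 2 * hom_minor + het
    hets = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    hm = (n_minor - hets) // 2
    hM = n - hm - hets
    logp = (gammaln(n + 1) - gammaln(hm + 1) - gammaln(hets + 1)
            - gammaln(hM + 1) + hets * math.log(2))
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    observed = probs[int(np.nonzero(hets == het)[0][0])]
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


def hwe_test(geno_controls: tuple[int, int, int],
             method: str = "auto") -> HweResult:
    """Hardy-Weinberg test on control genotype counts
    (hom-minor, het, hom-major).

    ``method`` is ``"exact"``, ``"chisq"``, or ``"auto"`` (exact for at
    most 1000 controls, chi-square above).  Monomorphic controls return
    p = 1 with the ``monomorphic`` note set.
    """
    hom_minor, het, hom_major = (int(x) for x in geno_controls)
    if min(hom_minor, het, hom_major) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = hom_minor + het + hom_major
    if n == 0:
        raise ValueError("no control genotypes")
    n_minor = 2 * hom_minor + het
    if n_minor == 0 or n_minor == 2 * n:
        return HweResult(p=1.0, method="monomorphic", monomorphic=True)
    if method == "auto":
        method = "exact" if n <= 1000 else "chisq"
    if method == "exact":
        return HweResult(p=_hwe_exact(hom_minor, het, hom_major),
                         method="exact")
    if method == "chisq":
        return HweResult(p=_hwe_chisq(hom_minor, het, hom_major),
                         method="chisq")
    raise ValueError(f"unknown HWE method {method!r}")


# ---------------------------------------------------------------------------
# minor-allele bookkeeping and eligibility
# ---------------------------------------------------------------------------

class MinorAlleleStats(NamedTuple):
    maf_pooled: float
    minor_allele_count: int
    n_total: int
    #: True when the curated effect allele is indeed the pooled minor allele.
    effect_is_minor: bool = True


def minor_allele_stats(collection: StudyCollection,
                       external_maf: Optional[float] = None
                       ) -> MinorAlleleStats:
    """Pooled minor-allele statistics across all studies with counts.

    The minor allele is fixed once from the pooled case+control counts so
    per-study orientation stays stable.  For summary-only collections an
    externally supplied MAF yields ``count = round(2 * N * maf)``; without
    one the statistics are unavailable and a ``ValueError`` is raised.
    """
    if not collection.studies:
        raise ValueError("empty collection")
    eff_count = 0
    total_alleles = 0
    n_subjects_counts = 0
    for s in collection.studies:
        p = s.payload
        if isinstance(p, GenotypeCounts):
            p = p.to_allele_counts()
        if isinstance(p, AlleleCounts):
            eff_count += p.case_minor + p.ctrl_minor
            total_alleles += (p.case_minor + p.case_major
                              + p.ctrl_minor + p.ctrl_major)
            n_subjects_counts += s.n_total
    n_all = sum(s.n_total for s in collection.studies)
    if total_alleles == 0:
        if external_maf is None:
            raise ValueError(
                "summary-only collection: minor-allele stats require an "
                "externally supplied MAF")
        return MinorAlleleStats(maf_pooled=external_maf,
                                minor_allele_count=round(2 * n_all * external_maf),
                                n_total=n_all)
    maf = eff_count / total_alleles
    effect_is_minor = maf <= 0.5
    if not effect_is_minor:
        maf, eff_count = 1.0 - maf, total_alleles - eff_count
    return MinorAlleleStats(maf_pooled=maf, minor_allele_count=eff_count,
                            n_total=n_all, effect_is_minor=effect_is_minor)


class Eligibility(NamedTuple):
    eligible: bool
    strata: frozenset[str]
    exclusions: tuple[str, ...]


#: Ethnicity strata that get their own meta-analysis when populated.
STRATUM_CODES = ("C", "A")


def apply_eligibility(collection: StudyCollection, *,
                      min_datasets: int = 4, min_stratum: int = 3,
                      maf_floor: float = 0.01) -> Eligibility:
    """Inclusion rules for meta-analysis.

    Overall: at least ``min_datasets`` independent datasets and a control
    minor-allele frequency of at least ``maf_floor`` in at least one study
    (checked on studies exposing counts; summary-only collections, e.g.
    quality-controlled GWAS data, satisfy the frequency criterion
    vacuously).  Strata (Caucasian, Asian): at least ``min_stratum``
    datasets with that code.
    """
    exclusions: list[str] = []
    k = collection.k
    if k < min_datasets:
        exclusions.append(
            f"only {k} independent datasets (minimum {min_datasets})")

    control_mafs: list[float] = []
    for s in collection.studies:
        p = s.payload
        if isinstance(p, GenotypeCounts):
            p = p.to_allele_counts()
        if isinstance(p, AlleleCounts):
            tot = p.ctrl_minor + p.ctrl_major
            if tot > 0:
                f = p.ctrl_minor / tot
                control_mafs.append(min(f, 1.0 - f))
    if control_mafs and max(control_mafs) < maf_floor:
        exclusions.append(
            f"control minor-allele frequency below {maf_floor} in every "
            "study with counts")

    strata = frozenset(
        code for code in STRATUM_CODES
        if len(collection.studies_in_stratum(code)) >= min_stratum)
    return Eligibility(eligible=not exclusions, strata=strata,
                       exclusions=tuple(exclusions))
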