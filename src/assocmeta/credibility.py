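"""Bayes factors, Venice/HuGENet grading, attributable risk, and ranking.

The approximate Bayes factor compares a spike-and-smear prior — a point
mass at no effect against a normal "smear" of non-null log odds ratios
with standard deviation ln(1.15), the log of a typical complex-disease
effect size — using only the summary log-OR and its standard error:

    logBF = log10(e) * (z^2 / 2) * W / (V + W) + 0.5 * log10(V / (V + W))

with z = log_or / se, V = se^2, W = (ln prior_or)^2.  Positive values
favour association.

The Venice interim criteria grade cumulative evidence A/B/C along three
axes — amount of evidence (minor-allele count), replication consistency
(I^2), and protection from bias (sensitivity and regression flags) —
and the composite grade is the worst component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats

from .bias import BiasResult
from .meta import MetaResult, SensitivityResult

_LOG10_E = math.log10(math.e)

#: Worst-of ordering for Venice grades.
_GRADE_ORDER = {"A": 0, "B": 1, "C": 2}


@dataclass(frozen=True)
class CredibilityAssessment:
    log_bf: Optional[float]
    amount_grade: str
    replication_grade: str
    bias_grade: str
    composite_grade: str
    low_or_flag: bool
    f_flag: bool
    hwe_flag: bool
    regr_flag: bool
    genome_wide: bool
    par: Optional[float] = None


def log_bayes_factor(log_or: float, se: Optional[float] = None,
                     p: Optional[float] = None,
                     prior_or: float = 1.15) -> float:
    """log10 Bayes factor of the spike-and-smear prior for one summary.

    Either ``se`` or a two-sided ``p`` must be given; with only ``p`` the
    standard error is recovered as |log_or| / z(p).
    """
    if prior_or <= 1.0:
        raise ValueError("prior_or must exceed 1")
    if se is None:
        if p is None:
            raise ValueError("either se or p is required")
        z = stats.norm.isf(p / 2.0)
        if not (z > 0 and math.isfinite(z)):
            raise ValueError(f"cannot invert p={p!r} to a z-score")
        se = abs(log_or) / z
    if se <= 0:
        raise ValueError("se must be positive")
    z = log_or / se
    if not math.isfinite(z):
        raise ValueError("non-finite z-score")
    v = se ** 2
    w = math.log(prior_or) ** 2
    return (_LOG10_E * (z ** 2 / 2.0) * w / (v + w)
            + 0.5 * math.log10(v / (v + w)))


def venice_grade(meta: MetaResult,
                 sens: Optional[SensitivityResult] = None,
                 bias: Optional[BiasResult] = None, *,
                 prior_or: float = 1.15,
                 gw_threshold: float = 5e-8,
                 amount_cutoffs: tuple[int, int] = (100, 1000),
                 i2_cutoffs: tuple[float, float] = (50.0, 75.0),
                 maf_controls: Optional[float] = None
                 ) -> CredibilityAssessment:
    """Venice/HuGENet interim grading of one meta-analysis result.

    Amount of evidence: A above ``amount_cutoffs[1]`` minor alleles, B in
    between, C below ``amount_cutoffs[0]``.  Replication: A/B/C by I^2
    against ``i2_cutoffs``.  Bias protection: C when any sensitivity or
    regression flag is raised, A otherwise.  The ``low OR`` band
    (0.87 <= OR < 1.15) is annotated but does not demote.
    """
    if meta.n_minor is None:
        raise ValueError("grading requires the minor-allele count")
    lo_n, hi_n = amount_cutoffs
    if meta.n_minor > hi_n:
        amount = "A"
    elif meta.n_minor >= lo_n:
        amount = "B"
    else:
        amount = "C"

    lo_i2, hi_i2 = i2_cutoffs
    if meta.i2 <= lo_i2:
        replication = "A"
    elif meta.i2 <= hi_i2:
        replication = "B"
    else:
        replication = "C"

    f_flag = bool(sens and sens.f_flag)
    hwe_flag = bool(sens and sens.hwe_flag)
    regr_flag = bool(bias and bias.regr_flag)
    bias_grade = "C" if (f_flag or hwe_flag or regr_flag) else "A"

    composite = max((amount, replication, bias_grade),
                    key=_GRADE_ORDER.__getitem__)
    or_ = meta.or_
    low_or = bool(0.87 <= or_ < 1.15)
    par = attributable_risk(maf_controls, or_) if maf_controls else None
    return CredibilityAssessment(
        log_bf=log_bayes_factor(meta.log_or, se=meta.se, prior_or=prior_or),
        amount_grade=amount, replication_grade=replication,
        bias_grade=bias_grade, composite_grade=composite,
        low_or_flag=low_or, f_flag=f_flag, hwe_flag=hwe_flag,
        regr_flag=regr_flag,
        genome_wide=bool(meta.p <= gw_threshold), par=par)


def attributable_risk(maf_controls: float, or_: float) -> float:
    """Population attributable risk via Levin's formula.

    ``PAR = f (OR - 1) / (1 + f (OR - 1))`` on the risk-allele frequency
    f; a protective OR is first inverted with f taken on the other
    allele.
    """
    if not (0.0 < maf_controls < 1.0):
        raise ValueError("maf_controls must be in (0, 1)")
    if or_ <= 0:
        raise ValueError("or_ must be positive")
    f, r = maf_controls, or_
    if r < 1.0:
        f, r = 1.0 - f, 1.0 / r
    return f * (r - 1.0) / (1.0 + f * (r - 1.0))


@dataclass(frozen=True)
class RankedResult:
    variant_id: str
    scope: str
    meta: MetaResult
    genome_wide: bool


def rank_results(results: Sequence[tuple[str, MetaResult]], *,
                 gw_threshold: float = 5e-8) -> list[RankedResult]:
    """Top-results ordering: ascending p (log10 scale, so extreme values
    stay distinguishable), ties broken by |log OR| descending, then
    variant id; flags genome-wide significance at ``gw_threshold``."""
    ranked = sorted(
        results,
        key=lambda vr: (vr[1].log10_p, -abs(vr[1].log_or), vr[0]))
    return [RankedResult(variant_id=v, scope=m.scope, meta=m,
                         genome_wide=bool(m.p <= gw_threshold))
            for v, m in ranked]
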