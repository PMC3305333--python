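"""Fixed- and random-effects synthesis of per-study allelic log odds ratios.

The random-effects model is DerSimonian-Laird: Cochran's Q from the
inverse-variance fixed-effect fit yields the method-of-moments
between-study variance

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)),

after which studies are re-weighted by 1 / (se_i^2 + tau^2).
Heterogeneity is summarised as I^2 = max(0, (Q - (k-1)) / Q) * 100 with a
test-based 95% interval on ln H = ln sqrt(Q / (k-1)).

Two-sided p-values come from the normal distribution of log-OR / se;
because summary p-values can be extreme (far below double underflow on
the OR scale), every result carries log10(p) computed via the normal
log-survival function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .effects import (StudyEffect, Z975, apply_eligibility, record_effect)
from .study_io import StudyCollection, StudyRecord

_LN10 = math.log(10.0)
_TINY_P = 5e-324  # smallest subnormal double; p is clamped here, log10_p is exact


class MetaError(ValueError):
    """Synthesis not possible on the given inputs."""


def two_sided_p(z: float) -> tuple[float, float]:
    """(p, log10 p) for a two-sided normal test statistic."""
    log_p = math.log(2.0) + stats.norm.logsf(abs(z))
    log10_p = log_p / _LN10
    return (max(math.exp(log_p), _TINY_P), log10_p)


@dataclass(frozen=True)
class MetaResult:
    """Summary of one meta-analysis scope."""

    scope: str
    method: str  # "FE", "DL-RE", or "weighted-Z"
    k: int
    log_or: float
    se: float
    p: float
    log10_p: float
    q_stat: float
    tau2: float
    i2: float
    i2_ci95: tuple[float, float]
    n_total: int = 0
    n_minor: Optional[int] = None

    @property
    def or_(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci95(self) -> tuple[float, float]:
        return (math.exp(self.log_or - Z975 * self.se),
                math.exp(self.log_or + Z975 * self.se))

    @property
    def z(self) -> float:
        return self.log_or / self.se


class CumulativePoint(NamedTuple):
    through_year: int
    k: int
    or_: float
    ci95: tuple[float, float]


@dataclass
class CumulativeTrace:
    """DerSimonian-Laird summaries of the first j studies, j = 2..k."""

    points: list[CumulativePoint] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)


def _check_effects(effects: Sequence[StudyEffect]) -> np.ndarray:
    if len(effects) < 2:
        raise MetaError(f"meta-analysis needs k >= 2 (got {len(effects)})")
    se = np.array([e.se for e in effects], dtype=float)
    if np.any(se <= 0) or not np.all(np.isfinite(se)):
        raise MetaError("all standard errors must be positive and finite")
    return se


def _totals(effects: Sequence[StudyEffect]) -> tuple[int, int]:
    n = sum(e.n_cases + e.n_controls for e in effects)
    n_minor = sum(e.minor_allele_count for e in effects)
    return n, n_minor


def i_squared(q_stat: float, k: int) -> float:
    """Point estimate of I^2 (percent), truncated at 0."""
    if q_stat <= 0:
        return 0.0
    return max(0.0, (q_stat - (k - 1)) / q_stat) * 100.0


def i_squared_ci(q_stat: float, k: int) -> tuple[float, tuple[float, float]]:
    """I^2 with its test-based 95% CI.

    The interval is built on ln H, H = sqrt(Q / (k-1)), using the
    large-sample standard error of ln H (one expression when Q > k,
    another when Q <= k), then mapped through I^2 = (H^2 - 1)/H^2 and
    truncated to [0, 100).
    """
    if k < 2:
        raise MetaError("I^2 needs k >= 2")
    i2 = i_squared(q_stat, k)
    q = max(q_stat, 1e-300)
    ln_h = 0.5 * max(0.0, math.log(q / (k - 1)))
    if q_stat > k:
        se_ln_h = 0.5 * (math.log(q_stat) - math.log(k - 1)) / (
            math.sqrt(2 * q_stat) - math.sqrt(2 * k - 3))
    elif k > 2:
        se_ln_h = math.sqrt(
            1.0 / (2 * (k - 2)) * (1.0 - 1.0 / (3 * (k - 2) ** 2)))
    else:
        # k = 2 with Q <= k: the large-sample se is undefined; the
        # interval is reported as maximally wide.
        se_ln_h = math.inf

    def to_i2(lnh: float) -> float:
        if not math.isfinite(lnh):
            return 100.0 if lnh > 0 else 0.0
        h2 = math.exp(2.0 * lnh)
        return max(0.0, (h2 - 1.0) / h2) * 100.0

    lo = to_i2(ln_h - Z975 * se_ln_h)
    hi = to_i2(ln_h + Z975 * se_ln_h)
    hi = min(hi, math.nextafter(100.0, 0.0))
    return i2, (lo, hi)


def fixed_effect_meta(effects: Sequence[StudyEffect],
                      scope: str = "all") -> MetaResult:
    """Inverse-variance fixed-effect synthesis."""
    se = _check_effects(effects)
    theta = np.array([e.log_or for e in effects], dtype=float)
    w = 1.0 / se ** 2
    sw = float(w.sum())
    mu = float((w * theta).sum() / sw)
    se_mu = sw ** -0.5
    q = float((w * (theta - mu) ** 2).sum())
    p, log10_p = two_sided_p(mu / se_mu)
    k = len(effects)
    i2, i2_ci = i_squared_ci(q, k)
    n, n_minor = _totals(effects)
    return MetaResult(scope=scope, method="FE", k=k, log_or=mu, se=se_mu,
                      p=p, log10_p=log10_p, q_stat=q, tau2=0.0, i2=i2,
                      i2_ci95=i2_ci, n_total=n, n_minor=n_minor or None)


def dl_random_effects_meta(effects: Sequence[StudyEffect],
                           scope: str = "all") -> MetaResult:
    """DerSimonian-Laird random-effects synthesis."""
    se = _check_effects(effects)
    theta = np.array([e.log_or for e in effects], dtype=float)
    w = 1.0 / se ** 2
    sw = float(w.sum())
    mu_fe = float((w * theta).sum() / sw)
    q = float((w * (theta - mu_fe) ** 2).sum())
    k = len(effects)
    denom = sw - float((w ** 2).sum()) / sw
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (se ** 2 + tau2)
    sw_star = float(w_star.sum())
    mu = float((w_star * theta).sum() / sw_star)
    se_mu = sw_star ** -0.5
    p, log10_p = two_sided_p(mu / se_mu)
    i2, i2_ci = i_squared_ci(q, k)
    n, n_minor = _totals(effects)
    return MetaResult(scope=scope, method="DL-RE", k=k, log_or=mu, se=se_mu,
                      p=p, log10_p=log10_p, q_stat=q, tau2=tau2, i2=i2,
                      i2_ci95=i2_ci, n_total=n, n_minor=n_minor or None)


def cumulative_meta(records: Sequence[StudyRecord],
                    effects: Sequence[StudyEffect]) -> CumulativeTrace:
    """Cumulative DerSimonian-Laird trace in publication order.

    Studies are sorted by (year, order index, study id); entry j is the
    random-effects summary of the first j studies, for j = 2..k, so the
    final point coincides with the full-collection result.
    """
    if len(records) != len(effects):
        raise MetaError("records and effects must align")
    order = sorted(range(len(records)), key=lambda i: records[i].sort_key)
    trace = CumulativeTrace()
    for j in range(2, len(order) + 1):
        idx = order[:j]
        res = dl_random_effects_meta([effects[i] for i in idx])
        trace.points.append(CumulativePoint(
            through_year=records[order[j - 1]].year, k=j,
            or_=res.or_, ci95=res.ci95))
    return trace


def stratified_meta(collection: StudyCollection,
                    effects: Optional[Sequence[StudyEffect]] = None, *,
                    min_datasets: int = 4, min_stratum: int = 3,
                    maf_floor: float = 0.01,
                    continuity: bool = True) -> dict[str, MetaResult]:
    """All-ethnicities plus per-stratum DerSimonian-Laird results.

    Returns a map from scope (``"all"``, ``"C"``, ``"A"``) to its result;
    ineligible strata are simply absent.  Studies outside the graded
    strata contribute only to the overall scope.
    """
    elig = apply_eligibility(collection, min_datasets=min_datasets,
                             min_stratum=min_stratum, maf_floor=maf_floor)
    if effects is None:
        effects = [record_effect(s, continuity=continuity)
                   for s in collection.studies]
    by_id = dict(zip((s.study_id for s in collection.studies), effects))
    out: dict[str, MetaResult] = {}
    if elig.eligible:
        out["all"] = dl_random_effects_meta(list(effects), scope="all")
    for code in sorted(elig.strata):
        sub = collection.studies_in_stratum(code)
        out[code] = dl_random_effects_meta(
            [by_id[s.study_id] for s in sub], scope=code)
    return out


class SensitivityResult(NamedTuple):
    excl_initial: Optional[MetaResult]
    excl_hwe: Optional[MetaResult]
    f_flag: bool
    hwe_flag: bool


def sensitivity_suite(records: Sequence[StudyRecord],
                      effects: Sequence[StudyEffect],
                      base: MetaResult, *,
                      alpha: float = 0.05,
                      hwe_alpha: float = 0.05) -> SensitivityResult:
    """Leave-out sensitivity re-analyses.

    ``F`` is set when a nominally significant base result loses
    significance after dropping the initial studies; ``HWE`` likewise
    after dropping studies whose controls violate Hardy-Weinberg
    equilibrium at ``hwe_alpha``.  A re-analysis is absent when fewer
    than two studies remain.
    """
    pairs = list(zip(records, effects))

    def rerun(keep) -> Optional[MetaResult]:
        sub = [e for r, e in pairs if keep(r, e)]
        if len(sub) < 2:
            return None
        return dl_random_effects_meta(sub, scope=base.scope)

    excl_initial = rerun(lambda r, e: not r.is_initial)
    excl_hwe = rerun(
        lambda r, e: e.hwe_p is None or e.hwe_p >= hwe_alpha)
    base_sig = base.p < alpha
    f_flag = bool(base_sig and excl_initial is not None
                  and excl_initial.p >= alpha)
    hwe_flag = bool(base_sig and excl_hwe is not None
                    and excl_hwe.p >= alpha)
    return SensitivityResult(excl_initial=excl_initial, excl_hwe=excl_hwe,
                             f_flag=f_flag, hwe_flag=hwe_flag)


class WeightedZResult(NamedTuple):
    z: float
    p: float
    log10_p: float


def weighted_z_meta(studies: Sequence[tuple[float, int, float]]
                    ) -> WeightedZResult:
    """Sample-size-weighted Stouffer combination of per-study p-values.

    Each study contributes ``(p, direction, n)`` with direction +1/-1;
    the combined statistic is Z = sum(sqrt(n_i) z_i) / sqrt(sum n_i).
    """
    if len(studies) < 2:
        raise MetaError("weighted-Z combination needs k >= 2")
    num = 0.0
    den = 0.0
    for p, direction, n in studies:
        if not (0.0 < p <= 1.0):
            raise MetaError(f"p-value out of range: {p!r}")
        if direction not in (1, -1):
            raise MetaError("direction must be +1 or -1")
        z = direction * stats.norm.isf(p / 2.0)
        num += math.sqrt(n) * z
        den += n
    z_comb = num / math.sqrt(den)
    p_comb, log10_p = two_sided_p(z_comb)
    return WeightedZResult(z=z_comb, p=p_comb, log10_p=log10_p)


def allelic_power(n_cases: int, n_controls: int, maf: float, or_: float,
                  alpha: float = 5e-8) -> float:
    """Power of the two-sided allelic test under a normal approximation.

    The control minor-allele frequency ``maf`` and odds ratio imply the
    case allele frequency; power is evaluated for the difference in
    allele frequencies at significance level ``alpha``.
    """
    if not (0.0 < maf <= 0.5):
        raise ValueError("maf must be in (0, 0.5]")
    if or_ <= 0 or not (0.0 < alpha <= 1.0):
        raise ValueError("or_ must be > 0 and alpha in (0, 1]")
    p0 = maf
    p1 = or_ * p0 / (1.0 - p0 + or_ * p0)
    sd = math.sqrt(p1 * (1 - p1) / n_cases + p0 * (1 - p0) / n_controls)
    ncp = (p1 - p0) / sd
    crit = stats.norm.isf(alpha / 2.0)
    return float(stats.norm.cdf(ncp - crit) + stats.norm.cdf(-ncp - crit))
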