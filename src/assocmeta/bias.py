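"""Small-study bias regression and sample-overlap variance inflation.

The small-study (publication) bias test is the modified funnel-asymmetry
regression for binary outcomes: per study the efficient score of the
log odds ratio, Z = a - E[a], and its hypergeometric variance V are
formed from the 2x2 allele-table margins; Z/sqrt(V) is regressed on
sqrt(V) and the intercept tested against zero with k-2 degrees of
freedom.  A non-zero intercept indicates that less precise studies
report systematically different effects.

Undetected sample overlap between datasets makes their estimates
positively correlated; the adjustment adds the weighted pairwise
covariances (shared-subject approximation) to the summary variance,
which can only widen confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .effects import StudyEffect
from .meta import MetaResult, two_sided_p
from .study_io import (AlleleCounts, GenotypeCounts, StudyCollection,
                       StudyRecord)


class BiasError(ValueError):
    """Bias diagnostics not computable on the given inputs."""


@dataclass
class BiasResult:
    """Funnel-asymmetry regression outcome plus overlap scenarios."""

    harbord_intercept: float = float("nan")
    harbord_se: float = float("nan")
    harbord_t: float = float("nan")
    harbord_p: float = float("nan")
    k_used: int = 0
    k_skipped: int = 0  # summary-only studies without a 2x2 table
    regr_flag: bool = False
    #: overlap fraction -> (adjusted summary se, adjusted two-sided p)
    overlap_adjusted: dict[float, tuple[float, float]] = field(
        default_factory=dict)


def _score_and_variance(table: Sequence[float]) -> tuple[float, float]:
    a, b, c, d = (float(x) for x in table)
    n = a + b + c + d
    row1 = a + b          # case alleles
    row0 = c + d          # control alleles
    col1 = a + c          # effect-allele margin
    col0 = b + d
    z = a - row1 * col1 / n
    v = row1 * row0 * col1 * col0 / (n ** 2 * (n - 1))
    return z, v


def harbord_test(tables: Sequence[Sequence[float]], *,
                 alpha_bias: float = 0.10) -> BiasResult:
    """Modified regression test for small-study effects on 2x2 allele
    tables ``(case_minor, case_major, ctrl_minor, ctrl_major)``.

    Fits ordinary least squares of Z/sqrt(V) on sqrt(V) and performs a
    two-sided t-test on the intercept with k-2 df.  Raises
    :class:`BiasError` for k < 3 or a degenerate predictor (all
    precisions identical).
    """
    if len(tables) < 3:
        raise BiasError(f"regression test needs k >= 3 (got {len(tables)})")
    pts = [_score_and_variance(t) for t in tables]
    if any(v <= 0 for _, v in pts):
        raise BiasError("non-positive score variance in a table")
    x = np.array([math.sqrt(v) for _, v in pts])
    y = np.array([z / math.sqrt(v) for z, v in pts])
    if np.ptp(x) < 1e-12 * max(1.0, float(np.abs(x).max())):
        raise BiasError("degenerate regression: no variation in precision")
    fit = stats.linregress(x, y)
    k = len(tables)
    t_stat = fit.intercept / fit.intercept_stderr
    p = float(2.0 * stats.t.sf(abs(t_stat), df=k - 2))
    return BiasResult(harbord_intercept=float(fit.intercept),
                      harbord_se=float(fit.intercept_stderr),
                      harbord_t=float(t_stat), harbord_p=p, k_used=k,
                      regr_flag=bool(p < alpha_bias))


def harbord_from_records(records: Sequence[StudyRecord], *,
                         alpha_bias: float = 0.10) -> BiasResult:
    """Run the regression test on a collection's count payloads, skipping
    (and counting) summary-only studies."""
    tables = []
    skipped = 0
    for s in records:
        p = s.payload
        if isinstance(p, GenotypeCounts):
            p = p.to_allele_counts()
        if isinstance(p, AlleleCounts):
            tables.append((p.case_minor, p.case_major,
                           p.ctrl_minor, p.ctrl_major))
        else:
            skipped += 1
    res = harbord_test(tables, alpha_bias=alpha_bias)
    res.k_skipped = skipped
    return res


# ---------------------------------------------------------------------------
# sample-overlap adjustment
# ---------------------------------------------------------------------------

def overlap_correlation(n_i: tuple[int, int], n_j: tuple[int, int],
                        shared_cases: float, shared_controls: float) -> float:
    """Correlation between two studies' log-OR estimates induced by
    shared subjects (shared-subject approximation).

    ``n_i``/``n_j`` are (n_cases, n_controls) per study.
    """
    n_i1, n_i0 = n_i
    n_j1, n_j0 = n_j
    if shared_cases > min(n_i1, n_j1) or shared_controls > min(n_i0, n_j0):
        raise BiasError("shared subjects exceed a group size")
    rho = (shared_cases * math.sqrt(n_i0 * n_j0 / (n_i1 * n_j1))
           + shared_controls * math.sqrt(n_i1 * n_j1 / (n_i0 * n_j0))
           ) / math.sqrt((n_i1 + n_i0) * (n_j1 + n_j0))
    return rho


def overlap_adjusted_variance(
        effects: Sequence[StudyEffect],
        weights: Sequence[float],
        pair_overlap: dict[tuple[int, int], tuple[float, float]]
) -> float:
    """Summary standard error after adding weighted pairwise covariances
    of overlapping datasets to the summary variance.

    ``pair_overlap`` maps index pairs (i, j), i < j, to
    (shared_cases, shared_controls).  With no overlap the unadjusted
    inverse-variance se is reproduced exactly.
    """
    w = np.asarray(weights, dtype=float)
    se = np.array([e.se for e in effects])
    sw = w.sum()
    var = float((w ** 2 * se ** 2).sum())
    for (i, j), (s1, s0) in pair_overlap.items():
        if i == j:
            raise BiasError("overlap pair must involve two distinct studies")
        rho = overlap_correlation(
            (effects[i].n_cases, effects[i].n_controls),
            (effects[j].n_cases, effects[j].n_controls), s1, s0)
        cov = rho * se[i] * se[j]
        var += 2.0 * w[i] * w[j] * cov
    var /= sw ** 2
    if var <= 0:
        raise BiasError("overlap adjustment produced non-positive variance")
    return math.sqrt(var)


def country_overlap_scenarios(
        records: Sequence[StudyRecord],
        effects: Sequence[StudyEffect],
        base: MetaResult,
        fractions: Sequence[float] = (0.01, 0.05, 0.10)
) -> dict[float, tuple[float, float]]:
    """Hypothetical same-country overlap scenarios.

    For each fraction f, every pair of datasets from the same country is
    assumed to share f * min(group sizes) cases and controls; pairs of
    GWAS datasets are exempt (duplicate samples removed before
    synthesis).  Returns fraction -> (adjusted se, adjusted two-sided p)
    under the base random-effects weights.
    """
    if len(records) != len(effects):
        raise BiasError("records and effects must align")
    w = [1.0 / (e.se ** 2 + base.tau2) for e in effects]
    out: dict[float, tuple[float, float]] = {}
    for f in fractions:
        overlap: dict[tuple[int, int], tuple[float, float]] = {}
        for i in range(len(records)):
            for j in range(i + 1, len(records)):
                ri, rj = records[i], records[j]
                if ri.country != rj.country:
                    continue
                if ri.is_gwas and rj.is_gwas:
                    continue
                s1 = f * min(ri.n_cases, rj.n_cases)
                s0 = f * min(ri.n_controls, rj.n_controls)
                overlap[(i, j)] = (s1, s0)
        se_adj = overlap_adjusted_variance(effects, w, overlap)
        p_adj, _ = two_sided_p(base.log_or / se_adj)
        out[f] = (se_adj, p_adj)
    return out
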