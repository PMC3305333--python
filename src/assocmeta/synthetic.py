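"""Synthetic study collections with the structure the synthesis assumes.

Each simulated collection mimics the published record for one variant:
per-study true log odds ratios drawn from Normal(true_log_or, tau2),
control minor-allele frequency fixed at ``maf`` with the case frequency
implied by each study's odds ratio, genotype counts drawn under
Hardy-Weinberg equilibrium (distorted by a fixed inbreeding coefficient
for studies designated as HWE violators), GWAS datasets contributing
summary effects, and an optional one-sided suppression mechanism that
drops small non-significant studies — the classic funnel-asymmetry
mechanism.

All randomness flows through one ``numpy.random.Generator`` seeded from
the config; identical configs produce identical collections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

from .effects import record_effect
from .meta import dl_random_effects_meta
from .study_io import (GenotypeCounts, StudyCollection, StudyRecord,
                       SummaryEffect, VariantRecord)

#: Inbreeding coefficient used to distort control genotypes in studies
#: designated as HWE violators; large enough to be reliably detectable
#: at a few hundred controls.
HWE_VIOLATION_F = 0.2

_COUNTRY_POOL = ("USA", "Germany", "Japan", "France", "UK", "Italy",
                 "China", "Spain", "Sweden", "Canada")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one simulated study collection.

    Defaults emulate a typical curated meta-analysis corpus: a modest
    complex-disease effect (OR 1.15), mild between-study heterogeneity,
    ten datasets of a few hundred to a few thousand subjects each,
    predominantly Caucasian with an Asian minority, occasional
    Hardy-Weinberg violations, and no suppression or overlap unless
    switched on.
    """

    true_log_or: float = math.log(1.15)
    tau2: float = 0.01
    k: int = 10
    maf: float = 0.2
    n_cases_range: tuple[int, int] = (200, 2000)
    n_controls_range: tuple[int, int] = (200, 2000)
    ethnicity_mix: dict[str, float] = field(
        default_factory=lambda: {"C": 0.7, "A": 0.2, "O": 0.1})
    gwas_fraction: float = 0.2
    hwe_violation_rate: float = 0.0
    #: (p threshold, probability of dropping a small non-significant study)
    suppression: tuple[float, float] = (1.0, 0.0)
    overlap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not (0.0 < self.maf <= 0.5):
            raise ValueError("maf must be in (0, 0.5]")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if abs(sum(self.ethnicity_mix.values()) - 1.0) > 1e-9:
            raise ValueError("ethnicity proportions must sum to 1")
        for lo, hi in (self.n_cases_range, self.n_controls_range):
            if lo <= 0 or hi < lo:
                raise ValueError("sample-size ranges must be positive")
        if not (0.0 <= self.hwe_violation_rate <= 1.0):
            raise ValueError("hwe_violation_rate must be in [0, 1]")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must be in [0, 1)")


@dataclass(frozen=True)
class TruthRecord:
    """Generative ground truth kept alongside a simulated collection."""

    true_log_or: float
    tau2: float
    per_study_log_or: tuple[float, ...]
    hwe_violators: tuple[str, ...]
    suppressed: tuple[str, ...]
    overlap_fraction: float


def _hwe_genotype_probs(freq: float, f_inbreed: float = 0.0
                        ) -> tuple[float, float, float]:
    q, p = freq, 1.0 - freq
    het = 2 * p * q * (1 - f_inbreed)
    return (q * q + f_inbreed * p * q, het, p * p + f_inbreed * p * q)


def simulate_collection(cfg: SyntheticConfig, *,
                        variant_id: Optional[str] = None
                        ) -> tuple[StudyCollection, TruthRecord]:
    """Draw one study collection plus its ground truth.

    Non-GWAS studies carry genotype counts; GWAS studies carry summary
    effects (log-OR, Woolf se) computed from their own simulated counts,
    mirroring how GWAS enter a curated corpus.  When suppression is
    active, below-median-size studies whose own p exceeds the threshold
    are dropped with the configured probability (never GWAS, never the
    initial study).
    """
    rng = np.random.default_rng(cfg.seed)
    vid = variant_id or f"rs{1_000_000 + cfg.seed % 1_000_000}"
    variant = VariantRecord(
        variant_id=vid, locus=f"LOC_{vid}", chromosome="1",
        position=1 + cfg.seed % 10_000_000,
        allele_pair=("A", "G"), effect_allele="A")

    codes = list(cfg.ethnicity_mix)
    probs = np.array([cfg.ethnicity_mix[c] for c in codes])
    p0 = cfg.maf
    median_n = (np.mean(cfg.n_cases_range) + np.mean(cfg.n_controls_range))

    studies: list[StudyRecord] = []
    truths: list[float] = []
    violators: list[str] = []
    suppressed: list[str] = []
    thresh, drop_prob = cfg.suppression
    for i in range(cfg.k):
        theta = float(rng.normal(cfg.true_log_or, math.sqrt(cfg.tau2)))
        or_i = math.exp(theta)
        p1 = or_i * p0 / (1.0 - p0 + or_i * p0)
        if not (0.0 < p1 < 1.0):
            raise ValueError("infeasible config: case frequency out of (0,1)")
        n_cases = int(rng.integers(cfg.n_cases_range[0],
                                   cfg.n_cases_range[1] + 1))
        n_controls = int(rng.integers(cfg.n_controls_range[0],
                                      cfg.n_controls_range[1] + 1))
        is_gwas = bool(rng.random() < cfg.gwas_fraction) and i > 0
        violates = (not is_gwas) and bool(
            rng.random() < cfg.hwe_violation_rate)
        case_geno = rng.multinomial(n_cases, _hwe_genotype_probs(p1))
        ctrl_geno = rng.multinomial(
            n_controls,
            _hwe_genotype_probs(p0, HWE_VIOLATION_F if violates else 0.0))
        geno = GenotypeCounts(*(int(x) for x in case_geno),
                              *(int(x) for x in ctrl_geno))
        sid = f"{vid}_s{i:03d}"
        record = StudyRecord(
            study_id=sid, year=1998 + i, order_index=i,
            country=str(rng.choice(_COUNTRY_POOL)),
            ethnicity=str(rng.choice(codes, p=probs)),
            is_initial=(i == 0), is_gwas=is_gwas,
            payload=geno, n_cases=n_cases, n_controls=n_controls)
        if is_gwas:
            eff = record_effect(record)
            record = replace(record,
                             payload=SummaryEffect(eff.log_or, eff.se))
        if violates:
            violators.append(sid)

        keep = True
        if drop_prob > 0 and not is_gwas and i > 0:
            eff = record_effect(record)
            p_study, _ = _study_p(eff.log_or, eff.se)
            small = (n_cases + n_controls) < median_n
            if small and p_study > thresh and rng.random() < drop_prob:
                keep = False
        if keep:
            studies.append(record)
            truths.append(theta)
        else:
            suppressed.append(sid)

    collection = StudyCollection(variant=variant, studies=studies)
    truth = TruthRecord(
        true_log_or=cfg.true_log_or, tau2=cfg.tau2,
        per_study_log_or=tuple(truths),
        hwe_violators=tuple(v for v in violators
                            if any(s.study_id == v for s in studies)),
        suppressed=tuple(suppressed),
        overlap_fraction=cfg.overlap_fraction)
    return collection, truth


def _study_p(log_or: float, se: float) -> tuple[float, float]:
    z = abs(log_or) / se
    return float(2.0 * stats.norm.sf(z)), z


@dataclass(frozen=True)
class RecoveryReport:
    """Estimator behaviour over replicated simulated collections."""

    replicates: int
    mean_log_or: float
    bias: float
    mean_tau2: float
    coverage95: float
    type_i_error: float  # share of replicates with p < 0.05 (meaningful
                         # as a type-I error only when true_log_or = 0)
    mc_se_mean: float


def recovery_report(cfg: SyntheticConfig, replicates: int,
                    alpha: float = 0.05) -> RecoveryReport:
    """Replicate-simulate-estimate loop for the random-effects estimator.

    Reports the mean DerSimonian-Laird estimate and its bias, mean
    tau-hat^2, empirical 95% CI coverage of the true log-OR, and the
    rejection rate of the base test at ``alpha``.
    """
    if replicates < 100:
        raise ValueError("replicates must be >= 100 for stable summaries")
    root = np.random.default_rng(cfg.seed)
    seeds = root.integers(0, 2 ** 31 - 1, size=replicates)
    est = np.empty(replicates)
    tau2s = np.empty(replicates)
    covered = np.empty(replicates, dtype=bool)
    rejected = np.empty(replicates, dtype=bool)
    z = stats.norm.isf(alpha / 2.0)
    for r in range(replicates):
        coll, _ = simulate_collection(replace(cfg, seed=int(seeds[r])))
        effects = [record_effect(s) for s in coll.studies]
        res = dl_random_effects_meta(effects)
        est[r] = res.log_or
        tau2s[r] = res.tau2
        lo = res.log_or - z * res.se
        hi = res.log_or + z * res.se
        covered[r] = lo <= cfg.true_log_or <= hi
        rejected[r] = res.p < alpha
    return RecoveryReport(
        replicates=replicates,
        mean_log_or=float(est.mean()),
        bias=float(est.mean() - cfg.true_log_or),
        mean_tau2=float(tau2s.mean()),
        coverage95=float(covered.mean()),
        type_i_error=float(rejected.mean()),
        mc_se_mean=float(est.std(ddof=1) / math.sqrt(replicates)))
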