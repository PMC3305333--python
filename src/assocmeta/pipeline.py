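"""End-to-end orchestration: eligibility -> meta-analysis -> sensitivity
-> bias diagnostics -> credibility grading -> ranked report.

``run_pipeline`` reads a study table, analyses every eligible variant at
every eligible scope, and writes a results TSV, per-variant forest-plot
JSON, and a run log recording the configuration, input hash, and every
decision threshold.  Runs are deterministic given input and config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from . import bias as bias_mod
from .credibility import CredibilityAssessment, rank_results, venice_grade
from .effects import (StudyEffect, apply_eligibility, minor_allele_stats,
                      record_effect)
from .meta import (CumulativeTrace, MetaResult, SensitivityResult,
                   cumulative_meta, dl_random_effects_meta,
                   fixed_effect_meta, sensitivity_suite, stratified_meta)
from .study_io import (ResultRow, StudyCollection, read_study_table,
                       validate_collection, write_forest_json,
                       write_results_table)

log = logging.getLogger("assocmeta")


@dataclass(frozen=True)
class PipelineConfig:
    """All decision thresholds of the synthesis, serialized with every run."""

    min_datasets: int = 4
    min_stratum: int = 3
    maf_floor: float = 0.01
    hwe_alpha: float = 0.05
    gw_threshold: float = 5e-8
    sig_alpha: float = 0.05
    bias_alpha: float = 0.10
    prior_or: float = 1.15
    overlap_fractions: tuple[float, ...] = (0.01, 0.05, 0.10)
    continuity_correction: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("maf_floor", "hwe_alpha", "gw_threshold", "sig_alpha",
                     "bias_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.min_datasets < 2 or self.min_stratum < 2:
            raise ValueError("dataset minima must be >= 2")
        if self.prior_or <= 1.0:
            raise ValueError("prior_or must exceed 1")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "overlap_fractions" in data:
            data["overlap_fractions"] = tuple(data["overlap_fractions"])
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        data = dataclasses.asdict(self)
        data["overlap_fractions"] = list(self.overlap_fractions)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class VariantAnalysis:
    """Everything computed for one variant."""

    collection: StudyCollection
    eligible: bool
    exclusions: tuple[str, ...]
    effects: list[StudyEffect] = field(default_factory=list)
    results: dict[str, MetaResult] = field(default_factory=dict)  # by scope
    fe_result: Optional[MetaResult] = None
    cumulative: Optional[CumulativeTrace] = None
    sensitivity: Optional[SensitivityResult] = None
    bias: Optional[bias_mod.BiasResult] = None
    credibility: dict[str, CredibilityAssessment] = field(
        default_factory=dict)
    maf_pooled: Optional[float] = None


def analyse_collection(collection: StudyCollection,
                       config: PipelineConfig) -> VariantAnalysis:
    """Run the full per-variant analysis chain."""
    findings = validate_collection(collection)
    if findings:
        raise ValueError(
            f"{collection.variant.variant_id}: invalid collection: "
            + "; ".join(findings))
    elig = apply_eligibility(collection,
                             min_datasets=config.min_datasets,
                             min_stratum=config.min_stratum,
                             maf_floor=config.maf_floor)
    va = VariantAnalysis(collection=collection, eligible=elig.eligible,
                         exclusions=elig.exclusions)
    if not elig.eligible:
        return va

    effects = [record_effect(s, continuity=config.continuity_correction)
               for s in collection.studies]
    va.effects = effects
    try:
        stats_ma = minor_allele_stats(collection)
        va.maf_pooled = stats_ma.maf_pooled
        n_minor = stats_ma.minor_allele_count
    except ValueError:
        n_minor = None

    va.results = stratified_meta(
        collection, effects, min_datasets=config.min_datasets,
        min_stratum=config.min_stratum, maf_floor=config.maf_floor)
    base = va.results["all"]
    if n_minor is not None:
        va.results["all"] = dataclasses.replace(base, n_minor=n_minor)
        base = va.results["all"]
    va.fe_result = fixed_effect_meta(effects)
    va.cumulative = cumulative_meta(collection.studies, effects)
    va.sensitivity = sensitivity_suite(
        collection.studies, effects, base,
        alpha=config.sig_alpha, hwe_alpha=config.hwe_alpha)

    if base.p < config.sig_alpha:
        try:
            va.bias = bias_mod.harbord_from_records(
                collection.studies, alpha_bias=config.bias_alpha)
        except bias_mod.BiasError as exc:
            log.info("%s: regression test skipped (%s)",
                     collection.variant.variant_id, exc)
        overlap = bias_mod.country_overlap_scenarios(
            collection.studies, effects, base,
            fractions=config.overlap_fractions)
        if va.bias is None:
            va.bias = bias_mod.BiasResult()
        va.bias.overlap_adjusted = overlap

        for scope, res in va.results.items():
            nm = res.n_minor if res.n_minor is not None else n_minor
            if res.p >= config.sig_alpha or nm is None:
                continue  # only nominally significant results are graded
            va.credibility[scope] = venice_grade(
                dataclasses.replace(res, n_minor=nm),
                va.sensitivity if scope == "all" else None,
                va.bias if scope == "all" else None,
                prior_or=config.prior_or,
                gw_threshold=config.gw_threshold,
                maf_controls=va.maf_pooled)
    return va


def _result_rows(analyses: Sequence[VariantAnalysis],
                 config: PipelineConfig) -> list[ResultRow]:
    rows: list[ResultRow] = []
    for va in analyses:
        vid = va.collection.variant.variant_id
        for scope in sorted(va.results, key=lambda s: (s != "all", s)):
            res = va.results[scope]
            cred = va.credibility.get(scope)
            flags = []
            if cred:
                if cred.low_or_flag:
                    flags.append("LowOR")
                if cred.f_flag:
                    flags.append("F")
                if cred.hwe_flag:
                    flags.append("HWE")
                if cred.regr_flag:
                    flags.append("Regr")
            rows.append(ResultRow(
                variant=vid, scope=scope, k=res.k, n_total=res.n_total,
                n_minor=res.n_minor, or_=res.or_, ci95=res.ci95, p=res.p,
                i2=res.i2, i2_ci95=res.i2_ci95, tau2=res.tau2,
                grade=cred.composite_grade if cred else None,
                log_bf=cred.log_bf if cred else None,
                flags=tuple(flags),
                genome_wide=bool(res.p <= config.gw_threshold)))
    return rows


def _forest_payload(va: VariantAnalysis) -> tuple[list[dict], dict]:
    base = va.results["all"]
    w = [1.0 / (e.se ** 2 + base.tau2) for e in va.effects]
    sw = sum(w)
    entries = [
        {"study": s.study_id, "year": s.year, "ethnicity": s.ethnicity,
         "or": round(e.or_, 6), "ci95": [round(x, 6) for x in e.ci95],
         "weight_pct": round(100.0 * wi / sw, 3)}
        for s, e, wi in zip(va.collection.studies, va.effects, w)]
    summary = {"or": round(base.or_, 6),
               "ci95": [round(x, 6) for x in base.ci95],
               "k": base.k, "i2": round(base.i2, 2),
               "cumulative": [
                   {"through_year": pt.through_year, "k": pt.k,
                    "or": round(pt.or_, 6),
                    "ci95": [round(x, 6) for x in pt.ci95]}
                   for pt in (va.cumulative.points if va.cumulative else [])]}
    return entries, summary


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(input_path: Union[str, Path],
                 config: PipelineConfig,
                 out_dir: Union[str, Path]) -> list[VariantAnalysis]:
    """Analyse every variant in a study table and write all artifacts.

    Outputs in ``out_dir``: ``results.tsv`` (one row per analysed scope,
    ranked), ``forest/<variant>.json``, ``exclusions.tsv``,
    ``config.yaml`` and ``run_log.json``.
    """
    input_path = Path(input_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    collections = read_study_table(input_path)

    analyses = [analyse_collection(c, config) for c in collections]
    eligible = [va for va in analyses if va.eligible]
    if not eligible:
        log.warning("no variant met the eligibility rules; writing an "
                    "empty results table")

    # rank by the overall-scope p-value; stratified rows follow their variant
    ranked = rank_results(
        [(va.collection.variant.variant_id, va.results["all"])
         for va in eligible], gw_threshold=config.gw_threshold)
    order = {r.variant_id: i for i, r in enumerate(ranked)}
    eligible.sort(key=lambda va: order[va.collection.variant.variant_id])

    rows = _result_rows(eligible, config)
    write_results_table(rows, out_dir / "results.tsv")

    forest_dir = out_dir / "forest"
    forest_dir.mkdir(exist_ok=True)
    for va in eligible:
        entries, summary = _forest_payload(va)
        write_forest_json(va.collection.variant, entries, summary,
                          forest_dir / f"{va.collection.variant.variant_id}.json")

    with open(out_dir / "exclusions.tsv", "w") as fh:
        fh.write("variant\treason\n")
        for va in analyses:
            for reason in va.exclusions:
                fh.write(f"{va.collection.variant.variant_id}\t{reason}\n")

    config.to_yaml(out_dir / "config.yaml")
    run_log = {
        "input": str(input_path),
        "input_sha256": _sha256(input_path),
        "config_sha256": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True,
                       default=list).encode()).hexdigest(),
        "n_variants": len(analyses),
        "n_eligible": len(eligible),
        "thresholds": {
            "minimum independent datasets": config.min_datasets,
            "minimum datasets per ethnicity stratum": config.min_stratum,
            "control minor-allele frequency floor": config.maf_floor,
            "Hardy-Weinberg violation alpha": config.hwe_alpha,
            "genome-wide significance threshold": config.gw_threshold,
            "nominal significance alpha": config.sig_alpha,
            "small-study regression alpha": config.bias_alpha,
            "prior odds ratio of the smear": config.prior_or,
        },
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=1,
                                                     sort_keys=True))
    return analyses


def simulate_corpus(configs: Sequence, out_dir: Union[str, Path]
                    ) -> Path:
    """Emit a synthetic study table (plus a truth sidecar) consumable by
    :func:`run_pipeline`.  ``configs`` is a sequence of
    :class:`~assocmeta.synthetic.SyntheticConfig`, one per variant."""
    from .study_io import write_study_table
    from .synthetic import simulate_collection

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    collections = []
    truths = {}
    for i, cfg in enumerate(configs):
        coll, truth = simulate_collection(cfg, variant_id=f"rs{100000 + i}")
        collections.append(coll)
        truths[coll.variant.variant_id] = {
            "true_log_or": truth.true_log_or,
            "tau2": truth.tau2,
            "hwe_violators": list(truth.hwe_violators),
            "suppressed": list(truth.suppressed),
            "overlap_fraction": truth.overlap_fraction,
        }
    table = out_dir / "studies.tsv"
    write_study_table(collections, table)
    (out_dir / "truth.json").write_text(json.dumps(truths, indent=1,
                                                   sort_keys=True))
    return table
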