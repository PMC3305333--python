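"""Data model and tabular I/O for allelic association study collections.

The unit of analysis is a :class:`StudyCollection`: one bi-allelic variant
together with all independent case-control datasets that genotyped it.  Each
dataset carries exactly one payload — allele counts, genotype counts, or a
precomputed log odds ratio with its standard error (typical for GWAS
summary data) — plus the metadata needed downstream: publication year,
country (for sample-overlap scenarios), ethnicity code, and flags marking
the initial report and GWAS-derived data.

Study tables are UTF-8 TSV with one row per (variant, study).  Results are
written as a TSV mirroring the layout of a cumulative-evidence overview
table (one row per meta-analysed scope) and round-trip through
:func:`read_results_table`.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

#: Recognised ancestry codes: Caucasian, Asian, African descent, Hispanic,
#: Other/mixed.  Unknown codes are coerced to "O" with a warning.
ETHNICITY_CODES = ("C", "A", "D", "H", "O")

#: Mandatory columns of the study-table TSV, in canonical order.
STUDY_TABLE_COLUMNS = [
    "variant_id", "locus", "chr", "pos_hg18", "allele_minor", "allele_major",
    "study_id", "year", "order", "country", "ethnicity", "is_initial",
    "is_gwas", "case_minor", "case_major", "ctrl_minor", "ctrl_major",
    "case_AA", "case_Aa", "case_aa", "ctrl_AA", "ctrl_Aa", "ctrl_aa",
    "log_or", "se", "n_cases", "n_controls",
]

RESULTS_COLUMNS = [
    "variant", "scope", "k", "N", "N_minor", "OR", "CI95", "P", "I2",
    "I2_CI", "tau2", "grade", "logBF", "flags", "genome_wide",
]


class SchemaError(ValueError):
    """Input table does not match the documented schema."""


class ValidationError(ValueError):
    """Input rows violate domain invariants (reported with row context)."""


# ---------------------------------------------------------------------------
# payloads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleCounts:
    """Minor/major allele counts in cases and controls."""

    case_minor: int
    case_major: int
    ctrl_minor: int
    ctrl_major: int

    def __post_init__(self) -> None:
        for name in ("case_minor", "case_major", "ctrl_minor", "ctrl_major"):
            if getattr(self, name) < 0:
                raise ValidationError(f"negative allele count in {name}")


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts (hom-minor, het, hom-major) in cases and controls."""

    case_hom_minor: int
    case_het: int
    case_hom_major: int
    ctrl_hom_minor: int
    ctrl_het: int
    ctrl_hom_major: int

    def __post_init__(self) -> None:
        for name in ("case_hom_minor", "case_het", "case_hom_major",
                     "ctrl_hom_minor", "ctrl_het", "ctrl_hom_major"):
            if getattr(self, name) < 0:
                raise ValidationError(f"negative genotype count in {name}")

    def to_allele_counts(self) -> AlleleCounts:
        return AlleleCounts(
            case_minor=2 * self.case_hom_minor + self.case_het,
            case_major=2 * self.case_hom_major + self.case_het,
            ctrl_minor=2 * self.ctrl_hom_minor + self.ctrl_het,
            ctrl_major=2 * self.ctrl_hom_major + self.ctrl_het,
        )

    @property
    def controls(self) -> tuple[int, int, int]:
        return (self.ctrl_hom_minor, self.ctrl_het, self.ctrl_hom_major)


@dataclass(frozen=True)
class SummaryEffect:
    """Precomputed per-study log odds ratio and standard error."""

    log_or: float
    se: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_or):
            raise ValidationError("summary log_or must be finite")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValidationError("summary se must be positive and finite")


Payload = Union[AlleleCounts, GenotypeCounts, SummaryEffect]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """A bi-allelic polymorphism with its genomic annotation (hg18)."""

    variant_id: str
    locus: str
    chromosome: str
    position: int
    allele_pair: tuple[str, str]  # (minor, major) as curated
    effect_allele: str

    def __post_init__(self) -> None:
        if self.allele_pair[0] == self.allele_pair[1]:
            raise ValidationError(
                f"{self.variant_id}: alleles must be distinct")
        if self.position <= 0:
            raise ValidationError(f"{self.variant_id}: position must be > 0")
        if self.effect_allele not in self.allele_pair:
            raise ValidationError(
                f"{self.variant_id}: effect allele not in allele pair")


def normalize_ethnicity(code: str) -> str:
    code = str(code).strip().upper()
    if code not in ETHNICITY_CODES:
        warnings.warn(
            f"unknown ethnicity code {code!r}; mapped to 'O'", stacklevel=3)
        return "O"
    return code


@dataclass(frozen=True)
class StudyRecord:
    """One independent case-control dataset for a variant."""

    study_id: str
    year: int
    order_index: int
    country: str
    ethnicity: str
    is_initial: bool
    is_gwas: bool
    payload: Payload
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "ethnicity", normalize_ethnicity(self.ethnicity))
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValidationError(
                f"{self.study_id}: n_cases and n_controls must be > 0")

    @property
    def sort_key(self) -> tuple[int, int, str]:
        return (self.year, self.order_index, self.study_id)

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls


@dataclass
class StudyCollection:
    """A variant plus its ordered, independent study records."""

    variant: VariantRecord
    studies: list[StudyRecord] = field(default_factory=list)
    independence_note: str = ""

    def __post_init__(self) -> None:
        self.studies = sorted(self.studies, key=lambda s: s.sort_key)

    @property
    def k(self) -> int:
        return len(self.studies)

    def studies_in_stratum(self, code: str) -> list[StudyRecord]:
        return [s for s in self.studies if s.ethnicity == code]


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_collection(collection: StudyCollection) -> list[str]:
    """Enumerate invariant violations; an empty list means the collection
    is internally consistent.  Pure: never raises, never mutates."""
    findings: list[str] = []
    seen: set[str] = set()
    for s in collection.studies:
        if s.study_id in seen:
            findings.append(f"duplicate study_id {s.study_id!r}")
        seen.add(s.study_id)
        p = s.payload
        if isinstance(p, GenotypeCounts):
            case_n = p.case_hom_minor + p.case_het + p.case_hom_major
            ctrl_n = p.ctrl_hom_minor + p.ctrl_het + p.ctrl_hom_major
            if case_n != s.n_cases:
                findings.append(
                    f"{s.study_id}: case genotype counts sum to {case_n}, "
                    f"expected n_cases={s.n_cases}")
            if ctrl_n != s.n_controls:
                findings.append(
                    f"{s.study_id}: control genotype counts sum to {ctrl_n}, "
                    f"expected n_controls={s.n_controls}")
        elif isinstance(p, AlleleCounts):
            if p.case_minor + p.case_major != 2 * s.n_cases:
                findings.append(
                    f"{s.study_id}: case allele counts do not sum to "
                    f"2*n_cases")
            if p.ctrl_minor + p.ctrl_major != 2 * s.n_controls:
                findings.append(
                    f"{s.study_id}: control allele counts do not sum to "
                    f"2*n_controls")
    return findings


# ---------------------------------------------------------------------------
# study-table reader
# ---------------------------------------------------------------------------

def _cell(row: pd.Series, col: str) -> Optional[float]:
    v = row.get(col)
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def _parse_payload(row: pd.Series, ctx: str) -> Payload:
    allele_cols = ["case_minor", "case_major", "ctrl_minor", "ctrl_major"]
    geno_cols = ["case_AA", "case_Aa", "case_aa", "ctrl_AA", "ctrl_Aa",
                 "ctrl_aa"]
    summ_cols = ["log_or", "se"]
    groups = {
        "allele": [_cell(row, c) for c in allele_cols],
        "genotype": [_cell(row, c) for c in geno_cols],
        "summary": [_cell(row, c) for c in summ_cols],
    }
    populated = [g for g, vals in groups.items()
                 if any(v is not None for v in vals)]
    if len(populated) != 1:
        raise ValidationError(
            f"{ctx}: payload ambiguous or absent "
            f"(populated column groups: {populated or 'none'})")
    kind = populated[0]
    vals = groups[kind]
    if any(v is None for v in vals):
        raise ValidationError(f"{ctx}: incomplete {kind} payload")
    if kind == "allele":
        ints = [int(v) for v in vals]
        if any(i < 0 for i in ints):
            raise ValidationError(f"{ctx}: negative allele count")
        return AlleleCounts(*ints)
    if kind == "genotype":
        ints = [int(v) for v in vals]
        if any(i < 0 for i in ints):
            raise ValidationError(f"{ctx}: negative genotype count")
        return GenotypeCounts(*ints)
    return SummaryEffect(log_or=vals[0], se=vals[1])


def _parse_flag(v: object) -> bool:
    return str(v).strip().lower() in {"1", "true", "t", "yes", "y"}


def read_study_table(path: Union[str, Path]) -> list[StudyCollection]:
    """Read a study-table TSV into one :class:`StudyCollection` per variant.

    Raises :class:`SchemaError` for missing mandatory columns and
    :class:`ValidationError` (naming the offending rows) for duplicate
    (variant, study) pairs, negative counts, or ambiguous payloads.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in STUDY_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    collections: dict[str, StudyCollection] = {}
    seen_pairs: set[tuple[str, str]] = set()
    problems: list[str] = []
    for idx, row in df.iterrows():
        ctx = f"row {idx + 2}"  # 1-based, counting the header line
        vid = row["variant_id"]
        sid = row["study_id"]
        if (vid, sid) in seen_pairs:
            raise ValidationError(
                f"{ctx}: duplicate (variant, study) pair ({vid}, {sid})")
        seen_pairs.add((vid, sid))
        try:
            payload = _parse_payload(row, ctx)
            record = StudyRecord(
                study_id=sid,
                year=int(row["year"]),
                order_index=int(row["order"]),
                country=row["country"],
                ethnicity=row["ethnicity"],
                is_initial=_parse_flag(row["is_initial"]),
                is_gwas=_parse_flag(row["is_gwas"]),
                payload=payload,
                n_cases=int(row["n_cases"]),
                n_controls=int(row["n_controls"]),
            )
        except ValidationError as exc:
            problems.append(str(exc))
            continue
        if vid not in collections:
            collections[vid] = StudyCollection(
                variant=VariantRecord(
                    variant_id=vid,
                    locus=row["locus"],
                    chromosome=row["chr"],
                    position=int(row["pos_hg18"]),
                    allele_pair=(row["allele_minor"], row["allele_major"]),
                    effect_allele=row["allele_minor"],
                ),
                studies=[],
            )
        collections[vid].studies.append(record)

    if problems:
        raise ValidationError(
            "unparseable study rows:\n  " + "\n  ".join(problems))
    out = list(collections.values())
    for c in out:
        c.studies.sort(key=lambda s: s.sort_key)
    return out


def write_study_table(collections: Iterable[StudyCollection],
                      path: Union[str, Path]) -> None:
    """Write collections back to the study-table TSV schema."""
    rows = []
    for c in collections:
        for s in c.studies:
            row = {col: "" for col in STUDY_TABLE_COLUMNS}
            row.update({
                "variant_id": c.variant.variant_id,
                "locus": c.variant.locus,
                "chr": c.variant.chromosome,
                "pos_hg18": c.variant.position,
                "allele_minor": c.variant.allele_pair[0],
                "allele_major": c.variant.allele_pair[1],
                "study_id": s.study_id,
                "year": s.year,
                "order": s.order_index,
                "country": s.country,
                "ethnicity": s.ethnicity,
                "is_initial": int(s.is_initial),
                "is_gwas": int(s.is_gwas),
                "n_cases": s.n_cases,
                "n_controls": s.n_controls,
            })
            p = s.payload
            if isinstance(p, AlleleCounts):
                row.update({"case_minor": p.case_minor,
                            "case_major": p.case_major,
                            "ctrl_minor": p.ctrl_minor,
                            "ctrl_major": p.ctrl_major})
            elif isinstance(p, GenotypeCounts):
                row.update({"case_AA": p.case_hom_minor,
                            "case_Aa": p.case_het,
                            "case_aa": p.case_hom_major,
                            "ctrl_AA": p.ctrl_hom_minor,
                            "ctrl_Aa": p.ctrl_het,
                            "ctrl_aa": p.ctrl_hom_major})
            else:
                row.update({"log_or": repr(p.log_or), "se": repr(p.se)})
            rows.append(row)
    pd.DataFrame(rows, columns=STUDY_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# results table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResultRow:
    """One meta-analysed scope of one variant, as printed in the results
    TSV.  Numeric fields are on the OR scale; absent credibility entries
    (ungraded, non-significant results) are ``None``."""

    variant: str
    scope: str
    k: int
    n_total: int
    n_minor: Optional[int]
    or_: float
    ci95: tuple[float, float]
    p: float
    i2: float
    i2_ci95: tuple[float, float]
    tau2: float
    grade: Optional[str]
    log_bf: Optional[float]
    flags: tuple[str, ...]
    genome_wide: bool


def _fmt_float(x: Optional[float], fmt: str) -> str:
    return "" if x is None else format(x, fmt)


def write_results_table(rows: Sequence[ResultRow],
                        path: Union[str, Path]) -> None:
    """Write the per-scope results TSV (header always present)."""
    out = []
    for r in rows:
        out.append({
            "variant": r.variant,
            "scope": r.scope,
            "k": r.k,
            "N": r.n_total,
            "N_minor": "" if r.n_minor is None else r.n_minor,
            "OR": format(r.or_, ".4f"),
            "CI95": f"{r.ci95[0]:.4f}-{r.ci95[1]:.4f}",
            "P": format(r.p, ".3e"),
            "I2": format(r.i2, ".1f"),
            "I2_CI": f"{r.i2_ci95[0]:.1f}-{r.i2_ci95[1]:.1f}",
            "tau2": format(r.tau2, ".6g"),
            "grade": r.grade or "",
            "logBF": _fmt_float(r.log_bf, ".2f"),
            "flags": ",".join(r.flags),
            "genome_wide": int(r.genome_wide),
        })
    pd.DataFrame(out, columns=RESULTS_COLUMNS).to_csv(
        path, sep="\t", index=False)


def read_results_table(path: Union[str, Path]) -> list[ResultRow]:
    """Parse a results TSV written by :func:`write_results_table`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in RESULTS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing results column(s): {', '.join(missing)}")
    rows = []
    for _, r in df.iterrows():
        lo, hi = r["CI95"].split("-")
        ilo, ihi = r["I2_CI"].split("-")
        rows.append(ResultRow(
            variant=r["variant"],
            scope=r["scope"],
            k=int(r["k"]),
            n_total=int(r["N"]),
            n_minor=int(r["N_minor"]) if r["N_minor"] != "" else None,
            or_=float(r["OR"]),
            ci95=(float(lo), float(hi)),
            p=float(r["P"]),
            i2=float(r["I2"]),
            i2_ci95=(float(ilo), float(ihi)),
            tau2=float(r["tau2"]),
            grade=r["grade"] or None,
            log_bf=float(r["logBF"]) if r["logBF"] != "" else None,
            flags=tuple(f for f in r["flags"].split(",") if f),
            genome_wide=bool(int(r["genome_wide"])),
        ))
    return rows


def write_forest_json(variant: VariantRecord,
                      entries: Sequence[dict],
                      summary: dict,
                      path: Union[str, Path]) -> None:
    """Export per-study forest-plot data (OR, CI, weight, label) plus the
    summary diamond as JSON."""
    doc = {
        "variant": variant.variant_id,
        "locus": variant.locus,
        "allele_contrast":
            f"{variant.effect_allele} vs. "
            f"{[a for a in variant.allele_pair if a != variant.effect_allele][0]}",
        "studies": list(entries),
        "summary": summary,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))
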