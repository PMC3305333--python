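import pytest
from hypothesis import settings

from assocmeta import (AlleleCounts, GenotypeCounts, StudyCollection,
                       StudyRecord, SummaryEffect, VariantRecord)

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


def make_variant(vid="rs1", minor="A", major="G"):
    return VariantRecord(variant_id=vid, locus="LOC1", chromosome="4",
                         position=90856624, allele_pair=(minor, major),
                         effect_allele=minor)


def make_study(sid, year=2005, order=0, ethnicity="C", country="USA",
               is_initial=False, is_gwas=False, payload=None,
               n_cases=100, n_controls=100):
    if payload is None:
        payload = AlleleCounts(60, 140, 50, 150)
    return StudyRecord(study_id=sid, year=year, order_index=order,
                       country=country, ethnicity=ethnicity,
                       is_initial=is_initial, is_gwas=is_gwas,
                       payload=payload, n_cases=n_cases,
                       n_controls=n_controls)


@pytest.fixture
def four_study_collection():
    """Four independent allele-count datasets with a common modest effect."""
    studies = [
        make_study("s1", year=2001, is_initial=True,
                   payload=AlleleCounts(70, 130, 50, 150)),
        make_study("s2", year=2003, country="Germany",
                   payload=AlleleCounts(65, 135, 52, 148)),
        make_study("s3", year=2004, country="Japan", ethnicity="A",
                   payload=AlleleCounts(68, 132, 55, 145)),
        make_study("s4", year=2006, country="France",
                   payload=AlleleCounts(72, 128, 48, 152)),
    ]
    return StudyCollection(variant=make_variant(), studies=studies)


@pytest.fixture
def genotype_study():
    """One genotype-count dataset in Hardy-Weinberg equilibrium."""
    return make_study(
        "g1", payload=GenotypeCounts(12, 56, 82, 9, 48, 93),
        n_cases=150, n_controls=150)


@pytest.fixture
def summary_study():
    return make_study("gwas1", is_gwas=True,
                      payload=SummaryEffect(0.14, 0.05),
                      n_cases=2000, n_controls=4000)
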