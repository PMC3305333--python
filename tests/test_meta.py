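"""Fixed/random-effects synthesis, heterogeneity, cumulative and
stratified analyses, weighted-Z combination, and allelic power."""

import math
import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, strategies as st

from assocmeta import (MetaError, StudyCollection, StudyEffect,
                       allelic_power, cumulative_meta,
                       dl_random_effects_meta, fixed_effect_meta,
                       i_squared_ci, record_effect, sensitivity_suite,
                       stratified_meta, weighted_z_meta)
from assocmeta.study_io import AlleleCounts

from conftest import make_study, make_variant


def eff(log_or, se=0.1):
    return StudyEffect(log_or=log_or, se=se)


class TestFixedEffect:
    def test_replication_shrinks_se_by_sqrt2(self):
        r = fixed_effect_meta([eff(0.2), eff(0.2)])
        assert r.or_ == pytest.approx(math.exp(0.2))
        assert r.se == pytest.approx(0.1 / math.sqrt(2), rel=1e-12)

    def test_inverse_variance_arithmetic(self):
        r = fixed_effect_meta([eff(0.0), eff(0.2)])
        assert r.or_ == pytest.approx(math.exp(0.1), abs=5e-4)
        assert r.ci95 == pytest.approx((0.962, 1.270), abs=5e-3)

    def test_single_study_rejected(self):
        with pytest.raises(MetaError):
            fixed_effect_meta([eff(0.2)])

    def test_nonpositive_se_rejected(self):
        with pytest.raises(MetaError):
            fixed_effect_meta([eff(0.2), StudyEffect(0.1, 0.0)])


class TestDerSimonianLaird:
    def test_homogeneous_studies_collapse_to_common_effect(self):
        r = dl_random_effects_meta([eff(0.2)] * 4)
        assert r.tau2 == 0.0 and r.i2 == 0.0
        assert r.or_ == pytest.approx(math.exp(0.2))

    def test_hand_computed_instance_to_1e12(self):
        # w = 100 each; FE mean 0.25; Q = 5; tau2 = 2/300; w* = 60
        r = dl_random_effects_meta([eff(x) for x in (0.2, 0.3, 0.1, 0.4)])
        assert r.q_stat == pytest.approx(5.0, abs=1e-12)
        assert r.tau2 == pytest.approx(2 / 300, abs=1e-12)
        assert r.log_or == pytest.approx(0.25, abs=1e-12)
        assert r.se == pytest.approx(1 / math.sqrt(240), abs=1e-12)
        assert r.i2 == pytest.approx(40.0, abs=1e-12)

    def test_unequal_weights_match_hand_arithmetic(self):
        # independent hand computation with w = 1/se^2
        effects = [eff(0.10, 0.05), eff(0.40, 0.10), eff(-0.05, 0.20)]
        w = np.array([400.0, 100.0, 25.0])
        theta = np.array([0.10, 0.40, -0.05])
        mu_fe = (w * theta).sum() / w.sum()
        q = float((w * (theta - mu_fe) ** 2).sum())
        tau2 = max(0.0, (q - 2) / (w.sum() - (w ** 2).sum() / w.sum()))
        w_star = 1.0 / (1.0 / w + tau2)
        mu = float((w_star * theta).sum() / w_star.sum())
        r = dl_random_effects_meta(effects)
        assert r.q_stat == pytest.approx(q, abs=1e-12)
        assert r.tau2 == pytest.approx(tau2, abs=1e-12)
        assert r.log_or == pytest.approx(mu, abs=1e-12)
        assert r.se == pytest.approx(w_star.sum() ** -0.5, abs=1e-12)

    def test_summary_or_is_geometric_mean_of_ci(self):
        r = dl_random_effects_meta([eff(x, s) for x, s in
                                    [(1.3, 0.2), (1.2, 0.15), (1.1, 0.3)]])
        lo, hi = r.ci95
        assert math.sqrt(lo * hi) == pytest.approx(r.or_, rel=1e-12)

    def test_re_se_never_below_fe_se(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            k = int(rng.integers(2, 12))
            effects = [eff(float(rng.normal(0, 0.3)),
                           float(rng.uniform(0.02, 0.5))) for _ in range(k)]
            fe = fixed_effect_meta(effects)
            re = dl_random_effects_meta(effects)
            assert re.se >= fe.se - 1e-15
            if re.tau2 == 0.0:
                assert re.se == pytest.approx(fe.se, rel=1e-12)
                assert re.log_or == pytest.approx(fe.log_or, rel=1e-9)

    def test_agrees_with_metafor_reference(self):
        """Cross-check against the DL implementation in R's metafor."""
        effects = [eff(0.11, 0.07), eff(0.32, 0.12), eff(-0.04, 0.21),
                   eff(0.18, 0.05), eff(0.25, 0.15)]
        yi = ",".join(str(e.log_or) for e in effects)
        vi = ",".join(str(e.se ** 2) for e in effects)
        script = textwrap.dedent(f"""
            suppressMessages(library(metafor))
            f <- rma(yi=c({yi}), vi=c({vi}), method="DL")
            cat(sprintf("%.12f %.12f %.12f %.12f\\n",
                        f$beta[1], f$se, f$tau2, f$QE))
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True, timeout=120)
        beta, se, tau2, q = (float(x) for x in out.stdout.split())
        r = dl_random_effects_meta(effects)
        assert r.log_or == pytest.approx(beta, abs=1e-9)
        assert r.se == pytest.approx(se, abs=1e-9)
        assert r.tau2 == pytest.approx(tau2, abs=1e-9)
        assert r.q_stat == pytest.approx(q, abs=1e-9)


class TestISquared:
    @pytest.mark.parametrize("q,k,expected", [
        (3.0, 4, 0.0),     # Q at or below df truncates to zero
        (5.0, 4, 40.0),
        (20.0, 11, 50.0),
    ])
    def test_point_estimate(self, q, k, expected):
        i2, _ = i_squared_ci(q, k)
        assert i2 == pytest.approx(expected, abs=1e-12)

    def test_ci_brackets_point_estimate(self):
        for q, k in [(5.0, 4), (22.58, 15), (2.0, 6), (40.0, 10)]:
            i2, (lo, hi) = i_squared_ci(q, k)
            assert 0.0 <= lo <= i2 <= hi < 100.0

    def test_reproduces_published_style_interval(self):
        # I2 = 38% over 15 studies carries a test-based CI of about (0, 66)
        i2, (lo, hi) = i_squared_ci(22.58, 15)
        assert i2 == pytest.approx(38.0, abs=0.1)
        assert lo == pytest.approx(0.0, abs=0.5)
        assert hi == pytest.approx(66.5, abs=1.0)


class TestCumulative:
    def test_trace_length_and_final_point(self, four_study_collection):
        effects = [record_effect(s) for s in four_study_collection.studies]
        trace = cumulative_meta(four_study_collection.studies, effects)
        assert len(trace) == four_study_collection.k - 1
        full = dl_random_effects_meta(effects)
        assert trace.points[-1].or_ == full.or_          # bit-identical
        assert trace.points[-1].ci95 == full.ci95
        assert [pt.k for pt in trace.points] == [2, 3, 4]

    def test_homogeneous_studies_give_flat_trace(self):
        studies = [make_study(f"s{i}", year=2000 + i) for i in range(5)]
        effects = [eff(0.2)] * 5
        trace = cumulative_meta(studies, effects)
        assert all(pt.or_ == pytest.approx(math.exp(0.2))
                   for pt in trace.points)

    def test_input_order_does_not_matter(self, four_study_collection):
        studies = four_study_collection.studies
        effects = [record_effect(s) for s in studies]
        fwd = cumulative_meta(studies, effects)
        rev = cumulative_meta(studies[::-1], effects[::-1])
        assert fwd == rev


class TestStratified:
    def _mixed_collection(self, n_c, n_a, n_o=0):
        studies = (
            [make_study(f"c{i}", ethnicity="C",
                        payload=AlleleCounts(60 + i, 140 - i, 50, 150))
             for i in range(n_c)]
            + [make_study(f"a{i}", ethnicity="A",
                          payload=AlleleCounts(64 + i, 136 - i, 52, 148))
               for i in range(n_a)]
            + [make_study(f"o{i}", ethnicity="O") for i in range(n_o)])
        return StudyCollection(variant=make_variant(), studies=studies)

    def test_both_strata_when_populated(self):
        res = stratified_meta(self._mixed_collection(3, 4))
        assert set(res) == {"all", "C", "A"}
        assert res["C"].k == 3 and res["A"].k == 4 and res["all"].k == 7

    def test_thin_stratum_absent(self):
        res = stratified_meta(self._mixed_collection(2, 4))
        assert set(res) == {"all", "A"}

    def test_other_ethnicities_only_in_overall(self):
        res = stratified_meta(self._mixed_collection(3, 3, n_o=2))
        assert set(res) == {"all", "C", "A"}
        assert res["all"].k == 8


class TestSensitivity:
    def test_no_initial_study_keeps_base(self, four_study_collection):
        studies = [s for s in four_study_collection.studies]
        effects = [record_effect(s) for s in studies]
        base = dl_random_effects_meta(effects)
        # rebuild without any initial flag
        studies = [make_study(s.study_id, year=s.year, payload=s.payload)
                   for s in studies]
        sens = sensitivity_suite(studies, effects, base)
        assert not sens.f_flag
        assert sens.excl_initial.log_or == pytest.approx(base.log_or)

    def test_dominant_initial_study_sets_f_flag(self):
        # one huge significant initial study among tiny null ones
        studies = [make_study("init", year=2000, is_initial=True),
                   make_study("s1", year=2001), make_study("s2", year=2002),
                   make_study("s3", year=2003)]
        effects = [StudyEffect(0.30, 0.03), StudyEffect(0.0, 0.4),
                   StudyEffect(0.05, 0.4), StudyEffect(-0.02, 0.4)]
        base = dl_random_effects_meta(effects)
        assert base.p < 0.05
        sens = sensitivity_suite(studies, effects, base)
        assert sens.f_flag and sens.excl_initial.p >= 0.05

    def test_hwe_violators_excluded(self):
        studies = [make_study(f"s{i}", year=2000 + i) for i in range(4)]
        effects = [StudyEffect(0.25, 0.05, hwe_p=0.001),
                   StudyEffect(0.01, 0.08), StudyEffect(0.02, 0.08),
                   StudyEffect(-0.01, 0.08)]
        base = dl_random_effects_meta(effects)
        sens = sensitivity_suite(studies, effects, base)
        assert sens.excl_hwe.k == 3
        if base.p < 0.05 and sens.excl_hwe.p >= 0.05:
            assert sens.hwe_flag

    def test_too_few_remaining_studies_absent(self):
        studies = [make_study("a", is_initial=True),
                   make_study("b", is_initial=True), make_study("c")]
        effects = [eff(0.2), eff(0.3), eff(0.1)]
        base = dl_random_effects_meta(effects)
        sens = sensitivity_suite(studies, effects, base)
        assert sens.excl_initial is None


class TestWeightedZ:
    def test_stouffer_arithmetic(self):
        p_for_z2 = 0.04550026389635857  # two-sided p at z = 2
        res = weighted_z_meta([(p_for_z2, 1, 500), (p_for_z2, 1, 500)])
        assert res.z == pytest.approx(2.8284, abs=5e-4)
        assert res.p == pytest.approx(0.00468, abs=5e-5)

    def test_opposite_directions_cancel(self):
        p = 0.0455
        res = weighted_z_meta([(p, 1, 300), (p, -1, 300)])
        assert res.z == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_single_study_rejected(self):
        with pytest.raises(MetaError):
            weighted_z_meta([(0.01, 1, 100)])

    def test_zero_p_rejected(self):
        with pytest.raises(MetaError):
            weighted_z_meta([(0.0, 1, 100), (0.5, 1, 100)])

    @given(st.lists(st.tuples(st.floats(1e-6, 0.999),
                              st.sampled_from([1, -1])),
                    min_size=2, max_size=8))
    def test_equal_n_reduces_to_unweighted_stouffer(self, items):
        from scipy import stats
        studies = [(p, d, 250) for p, d in items]
        res = weighted_z_meta(studies)
        zs = [d * stats.norm.isf(p / 2) for p, d in items]
        assert res.z == pytest.approx(sum(zs) / math.sqrt(len(zs)),
                                      rel=1e-9, abs=1e-9)


class TestAllelicPower:
    def test_alpha_one_gives_certain_rejection(self):
        assert allelic_power(500, 500, 0.2, 1.2, alpha=1.0) == pytest.approx(
            1.0)

    def test_genome_wide_power_small_effect_rare_allele(self):
        power = allelic_power(20000, 20000, 0.05, 1.15, alpha=5e-8)
        assert power == pytest.approx(0.010, abs=2e-3)

    def test_monotone_in_sample_size(self):
        powers = [allelic_power(n, n, 0.2, 1.15, alpha=5e-8)
                  for n in (2000, 8000, 32000)]
        assert powers[0] < powers[1] < powers[2]
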