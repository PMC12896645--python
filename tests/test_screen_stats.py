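"""Filtering cascade and enrichment statistics: exact-enumeration Fisher
oracle, closed-form t-test fixtures, threshold nesting, and the partition
bookkeeping identities."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from visscreen.config import ScreenConfig
from visscreen.screen_stats import (
    coverage_tests,
    filter_replicate_concordance,
    filter_singletons,
    filter_treatment_concordance,
    fisher_exact_2x2,
    frequency_tests,
    screen_tests,
    select_candidates,
    student_t_test,
    summarize_partitions,
    verify_candidates,
)
from conftest import make_matrix, sample_frame


# ---------------------------------------------------------------------------
# Independent oracle for the two-sided Fisher test (scipy-free enumeration
# lives in the implementation; the library route is the cross-check, and an
# explicit enumeration here keeps the example values honest).
# ---------------------------------------------------------------------------

def fisher_oracle(a, b, c, d) -> Fraction:
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return Fraction(1)
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    return sum(
        Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
        if Fraction(comb(r1, k) * comb(r2, c1 - k), denom) <= p_obs
    )


class TestFisherExact:
    def test_identical_proportions_give_p_one(self):
        assert fisher_exact_2x2(2, 2, 2, 2) == pytest.approx(1.0)

    def test_two_extreme_tables(self):
        # (5,0,0,5): the two diagonal tables each carry 1/C(10,5) = 1/252
        assert fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(2 / 252, rel=1e-12)

    def test_uniquely_most_extreme_table(self):
        # all 15 treated detected, no controls: p = 1 / C(34, 15)
        assert fisher_exact_2x2(15, 0, 0, 19) == pytest.approx(
            1 / comb(34, 15), rel=1e-12
        )

    def test_zero_margin_returns_one(self):
        assert fisher_exact_2x2(0, 0, 3, 5) == 1.0
        assert fisher_exact_2x2(0, 4, 0, 5) == 1.0

    def test_symmetric_under_row_and_column_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 8, size=4)
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_exact_2x2(d, c, b, a), abs=1e-14
            )

    def test_agrees_with_scipy_reference(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            a, b, c, d = (int(x) for x in rng.integers(0, 10, size=4))
            expected = stats.fisher_exact([[a, b], [c, d]])[1]
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(expected, abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)


class TestStudentT:
    def test_identical_groups(self):
        t, p, ok = student_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ok and t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_closed_form_fixture(self):
        # pooled s2 = 1, SE = sqrt(2/3): t = -3/sqrt(2/3) = -3.67423...
        t, p, ok = student_t_test([1, 2, 3], [4, 5, 6])
        assert ok
        assert t == pytest.approx(-3 / np.sqrt(2 / 3), abs=1e-9)
        assert p == pytest.approx(2 * stats.t.sf(3 / np.sqrt(2 / 3), 4), abs=1e-9)
        assert p == pytest.approx(0.0213, abs=5e-4)

    def test_all_zero_groups(self):
        t, p, ok = student_t_test([0, 0, 0], [0, 0, 0])
        assert ok and t == 0.0 and p == 1.0

    def test_zero_variance_unequal_means_degenerate(self):
        t, p, ok = student_t_test([1, 1, 1], [2, 2, 2])
        assert ok and p == 0.0 and t < 0

    def test_small_group_not_computable(self):
        _, _, ok = student_t_test([1.0], [1.0, 2.0])
        assert not ok

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            x = rng.normal(size=rng.integers(2, 10))
            y = rng.normal(size=rng.integers(2, 10))
            t, p, _ = student_t_test(x, y)
            ref_t, ref_p = stats.ttest_ind(x, y, equal_var=True)
            assert t == pytest.approx(ref_t, abs=1e-9)
            assert p == pytest.approx(ref_p, abs=1e-9)


# ---------------------------------------------------------------------------
# Filtering cascade
# ---------------------------------------------------------------------------

class TestFilters:
    def samples(self):
        return sample_frame(
            [
                ("nc1", "NC", "pLN1"),
                ("nc2", "NC", "pLN2"),
                ("f1", "fulvestrant", "pLN1"),
                ("f2", "fulvestrant", "pLN2"),
                ("r1", "ribociclib", "pLN1"),
                ("r2", "ribociclib", "pLN2"),
            ]
        )

    def test_singleton_removed_doubleton_kept(self):
        m = make_matrix(
            {
                "L1": {"nc1": 5},                  # one sample -> removed
                "L2": {"nc1": 5, "f1": 2},         # two samples -> kept
                "L3": {},                          # zero samples -> kept (not a singleton)
            },
            self.samples(),
        )
        out = filter_singletons(m)
        assert set(out.detected.index) == {"L2", "L3"}

    def test_empty_matrix_passes_through(self):
        m = make_matrix({}, self.samples())
        assert len(filter_singletons(m).detected) == 0

    def test_replicate_concordance(self):
        m = make_matrix(
            {
                "L1": {"nc1": 3, "f1": 2, "r1": 1},   # pLN1 only -> removed
                "L2": {"nc1": 3, "f2": 2},            # both replicates -> kept
            },
            self.samples(),
        )
        out = filter_replicate_concordance(m)
        assert set(out.detected.index) == {"L2"}

    def test_replicate_filter_identity_when_all_concordant(self):
        m = make_matrix(
            {"L1": {"nc1": 1, "nc2": 1}, "L2": {"f1": 1, "r2": 1}}, self.samples()
        )
        out = filter_replicate_concordance(m)
        assert set(out.detected.index) == {"L1", "L2"}

    def test_missing_replicate_label_is_error(self):
        samples = self.samples()
        samples = samples[samples["biological_replicate"] == "pLN1"]
        m = make_matrix({"L1": {"nc1": 1}}, samples)
        with pytest.raises(ValueError, match="replicate"):
            filter_replicate_concordance(m)

    def test_treatment_concordance_rules(self):
        m = make_matrix(
            {
                # detected only in controls (both replicates) -> removed
                "L1": {"nc1": 2, "nc2": 2},
                # fulvestrant in both replicates -> kept
                "L2": {"f1": 1, "f2": 1},
                # cross-treatment mixing (fulv pLN1 + ribo pLN2) -> removed
                "L3": {"f1": 1, "r2": 1},
            },
            self.samples(),
        )
        out = filter_treatment_concordance(m)
        assert set(out.detected.index) == {"L2"}

    def test_filters_are_contractions_with_consistent_counts(self):
        rng = np.random.default_rng(3)
        counts = {
            f"L{i}": {
                s: int(rng.integers(0, 4))
                for s in self.samples().index
                if rng.random() < 0.5
            }
            for i in range(30)
        }
        m = make_matrix(counts, self.samples())
        m1 = filter_singletons(m)
        m2 = filter_replicate_concordance(m1)
        m3 = filter_treatment_concordance(m2)
        assert set(m3.detected.index) <= set(m2.detected.index) <= set(
            m1.detected.index
        ) <= set(m.detected.index)
        removed = (
            (len(m.detected) - len(m1.detected))
            + (len(m1.detected) - len(m2.detected))
            + (len(m2.detected) - len(m3.detected))
        )
        assert removed + len(m3.detected) == len(m.detected)


# ---------------------------------------------------------------------------
# Frequency and coverage tests
# ---------------------------------------------------------------------------

def screen_samples():
    spec = [(f"nc{i}", "NC", "pLN1" if i < 10 else "pLN2") for i in range(19)]
    spec += [(f"f{i}", "fulvestrant", "pLN1" if i < 8 else "pLN2") for i in range(15)]
    return sample_frame(spec)


class TestFrequencyTests:
    def test_absent_locus_p_one_direction_none(self):
        m = make_matrix({"L1": {}}, screen_samples())
        res = frequency_tests(m, "fulvestrant")
        assert res.loc["L1", "fisher_p"] == 1.0
        assert res.loc["L1", "freq_direction"] == "none"

    def test_exclusive_treated_locus_significant(self):
        m = make_matrix({"L1": {f"f{i}": 2 for i in range(15)}}, screen_samples())
        res = frequency_tests(m, "fulvestrant")
        assert res.loc["L1", "freq_direction"] == "exclusive_treated"
        assert res.loc["L1", "fisher_p"] == pytest.approx(1 / comb(34, 15), rel=1e-9)
        assert res.loc["L1", "freq_flag"] == "significant"

    def test_equal_proportions_ns(self):
        counts = {f"f{i}": 1 for i in range(3)}
        # 3/15 treated = 0.2; make controls ~0.2 too (not exactly representable;
        # use 19 * 0.2 -> choose equal fractions via all-detected)
        m = make_matrix(
            {"L1": {**{f"f{i}": 1 for i in range(15)}, **{f"nc{i}": 1 for i in range(19)}}},
            screen_samples(),
        )
        res = frequency_tests(m, "fulvestrant")
        assert res.loc["L1", "freq_direction"] == "none"
        assert res.loc["L1", "freq_flag"] == "ns"

    def test_missing_group_is_error(self):
        m = make_matrix({"L1": {}}, sample_frame([("s", "NC", "pLN1")]))
        with pytest.raises(ValueError, match="samples"):
            frequency_tests(m, "fulvestrant")

    def test_threshold_nesting(self):
        rng = np.random.default_rng(4)
        counts = {
            f"L{i}": {
                s: 1 for s in screen_samples().index if rng.random() < rng.uniform(0.1, 0.9)
            }
            for i in range(40)
        }
        m = make_matrix(counts, screen_samples())
        strict = ScreenConfig(p_exploratory=0.05, p_significant=0.05)
        relaxed = ScreenConfig()
        res_r = frequency_tests(m, "fulvestrant", relaxed)
        sig = set(res_r.index[res_r["fisher_p"] < 0.05])
        expl = set(res_r.index[res_r["fisher_p"] < 0.1])
        assert sig <= expl
        assert (res_r.loc[list(sig), "freq_flag"] == "significant").all()


class TestCoverageTests:
    def test_identical_rpm_everywhere_ns(self):
        m = make_matrix(
            {"L1": {s: 5 for s in screen_samples().index},
             "L2": {s: 5 for s in screen_samples().index}},
            screen_samples(),
        )
        res = coverage_tests(m, "fulvestrant")
        assert (res["cov_flag"] == "ns").all()

    def test_planted_enrichment_detected_as_enriched(self):
        counts = {
            "HOT": {**{f"f{i}": 90 for i in range(15)}, **{f"nc{i}": 10 for i in range(19)}},
            "BG": {**{f"f{i}": 10 for i in range(15)}, **{f"nc{i}": 90 for i in range(19)}},
        }
        m = make_matrix(counts, screen_samples())
        res = coverage_tests(m, "fulvestrant")
        assert res.loc["HOT", "cov_direction"] == "enriched"
        assert res.loc["HOT", "cov_flag"] == "significant"

    def test_depleted_locus_detected(self):
        counts = {
            "GONE": {f"nc{i}": 50 for i in range(19)},
            "BG": {**{f"f{i}": 100 for i in range(15)}, **{f"nc{i}": 50 for i in range(19)}},
        }
        m = make_matrix(counts, screen_samples())
        res = coverage_tests(m, "fulvestrant")
        assert res.loc["GONE", "cov_direction"] == "depleted"

    def test_detected_only_mode_flags_small_groups_ns(self):
        cfg = ScreenConfig(coverage_include_undetected=False)
        m = make_matrix({"L1": {"f0": 5, "nc0": 3, "nc1": 4}}, screen_samples())
        res = coverage_tests(m, "fulvestrant", cfg)
        assert res.loc["L1", "cov_flag"] == "ns"


# ---------------------------------------------------------------------------
# Candidate selection / verification
# ---------------------------------------------------------------------------

class TestCandidates:
    def results_fixture(self, qualifies: bool, direction="enriched"):
        row = {
            "treatment": "fulvestrant",
            "a": 10, "n_t": 15, "b": 1, "n_c": 19,
            "fisher_p": 0.01 if qualifies else 0.9,
            "freq_direction": direction,
            "freq_flag": "significant" if qualifies else "ns",
            "mean_rpm_treated": 10.0, "mean_rpm_control": 1.0,
            "t_stat": 1.0, "t_p": 0.5,
            "cov_direction": direction, "cov_flag": "ns",
        }
        return pd.DataFrame([row], index=pd.Index(["L1"], name="locus_id"))

    def test_no_qualifying_loci_empty_list(self):
        res = {"fulvestrant": self.results_fixture(False)}
        out = select_candidates(res, {"L1": "GENE1"})
        assert len(out) == 0

    def test_two_loci_one_gene_merged_with_both_treatments(self):
        fulv = self.results_fixture(True)
        ribo = self.results_fixture(True).assign(treatment="ribociclib")
        ribo.index = pd.Index(["L2"], name="locus_id")
        out = select_candidates(
            {"fulvestrant": fulv, "ribociclib": ribo}, {"L1": "GENE1", "L2": "GENE1"}
        )
        assert len(out) == 1
        assert out.iloc[0]["gene"] == "GENE1"
        assert out.iloc[0]["treatments"] == "fulvestrant,ribociclib"
        assert out.iloc[0]["supporting_loci"] == "L1,L2"

    def test_locus_qualifying_for_both_treatments_counted_once(self):
        fulv = self.results_fixture(True)
        ribo = self.results_fixture(True).assign(treatment="ribociclib")
        out = select_candidates(
            {"fulvestrant": fulv, "ribociclib": ribo}, {"L1": "GENE1"}
        )
        assert len(out) == 1 and out.iloc[0]["n_treatments"] == 2

    def test_depleted_locus_excluded_by_default_included_on_request(self):
        res = {"fulvestrant": self.results_fixture(True, direction="depleted")}
        assert len(select_candidates(res, {"L1": "G"})) == 0
        cfg = ScreenConfig(require_enriched=False)
        assert len(select_candidates(res, {"L1": "G"}, cfg)) == 1

    def test_unannotated_locus_keeps_its_id(self):
        res = {"fulvestrant": self.results_fixture(True)}
        out = select_candidates(res, {"L1": None})
        assert out.iloc[0]["gene"] == "L1"

    def verification_matrix(self, detected_groups):
        spec = [("a1", "abemaciclib", "pLN1"), ("p1", "palbociclib", "pLN1"),
                ("c1", "fulvestrant+ribociclib", "pLN1"), ("nc1", "NC", "pLN1")]
        counts = {"L1": {g: 1 for g in detected_groups}}
        return make_matrix(counts, sample_frame(spec))

    def candidates_frame(self):
        return pd.DataFrame(
            [{"gene": "G1", "supporting_loci": "L1", "treatments": "fulvestrant",
              "n_treatments": 1, "evidence": "fulvestrant:freq_significant"}]
        )

    VER = ("abemaciclib", "palbociclib", "fulvestrant+ribociclib")

    def test_all_groups(self):
        m = self.verification_matrix(["a1", "p1", "c1"])
        out = verify_candidates(self.candidates_frame(), m, self.VER)
        assert out.iloc[0]["verification_category"] == "all_groups"

    def test_none(self):
        m = self.verification_matrix([])
        out = verify_candidates(self.candidates_frame(), m, self.VER)
        assert out.iloc[0]["verification_category"] == "none"

    def test_one_group_boundary(self):
        m = self.verification_matrix(["p1"])
        out = verify_candidates(self.candidates_frame(), m, self.VER)
        assert out.iloc[0]["verification_category"] == "one_or_two_groups"

    def test_missing_verification_treatment_is_error(self):
        m = self.verification_matrix(["p1"])
        with pytest.raises(ValueError, match="absent"):
            verify_candidates(self.candidates_frame(), m, ("no-such-arm",))


# ---------------------------------------------------------------------------
# Partition bookkeeping
# ---------------------------------------------------------------------------

class TestSummarizePartitions:
    def test_cascade_retention(self):
        s = summarize_partitions(
            {"cascade": {"total": 3902, "exclusions": {"singletons": 3171, "discordant": 305}}}
        )
        assert s.values["cascade_retained"] == 426

    def test_category_total(self):
        s = summarize_partitions(
            {"freq": {"categories": {"tam": 61, "fulv": 9, "ribo": 14, "shared": 5}}}
        )
        assert s.values["freq_total"] == 89

    def test_empty_tallies_zero(self):
        s = summarize_partitions({"x": {"categories": {}}})
        assert s.values["x_total"] == 0

    def test_inconsistent_identity_raises_naming_stage(self):
        with pytest.raises(ValueError, match="cascade"):
            summarize_partitions(
                {"cascade": {"total": 100, "exclusions": {"a": 10}, "retained": 80}}
            )

    def test_expected_total_mismatch_raises(self):
        with pytest.raises(ValueError, match="expected total"):
            summarize_partitions(
                {"s": {"categories": {"a": 1, "b": 2}, "expected_total": 4}}
            )

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            summarize_partitions({"s": {"categories": {"a": -1}}})
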