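"""Filtering cascade: thresholds, binomial background test, tier composition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renovar.filtering import (
    FATE_BACKGROUND,
    FATE_NORMAL_DEPTH,
    FATE_NORMAL_VAF,
    FATE_OTHER_PATIENT_VAF,
    FATE_SNP,
    FATE_TUMOUR_DEPTH,
    FATE_TUMOUR_VAF,
    KEPT,
    CrossSampleReadMatrix,
    FilterConfig,
    VariantCall,
    background_binomial_pvalue,
    dataset_level_filter,
    pipeline_level_filter,
    run_cascade,
    sample_level_filter,
)
from renovar.simulate import SEQUENCING_ERROR, simulate_normal_comparison


def make_call(sample="T1", pos=100, tt=40, ta=10, nt=40, na=0, snp=False, **kw):
    return VariantCall(
        sample_id=sample, chrom="chr1", pos=pos, ref="C", alt="T",
        tumour_total=tt, tumour_alt=ta, normal_total=nt, normal_alt=na,
        is_snp_site=snp, **kw,
    )


class TestVariantCall:
    @pytest.mark.parametrize("kw", [
        dict(ta=50),          # alt > total
        dict(na=50),
    ])
    def test_count_invariants_enforced(self, kw):
        with pytest.raises(ValueError):
            make_call(**kw)

    def test_allele_validation(self):
        with pytest.raises(ValueError):
            VariantCall("T1", "chr1", 1, "C", "C", 10, 5, 10, 0)
        with pytest.raises(ValueError):
            VariantCall("T1", "chr1", 1, "N", "T", 10, 5, 10, 0)


class TestSampleLevelFilter:
    @pytest.mark.parametrize("call,expected_fate", [
        (make_call(tt=13, ta=5), FATE_TUMOUR_DEPTH),      # 13 < 14 discarded
        (make_call(tt=14, ta=5), KEPT),                   # exactly 14 kept
        (make_call(nt=9), FATE_NORMAL_DEPTH),
        (make_call(tt=20, ta=2, nt=30, na=0), KEPT),      # VAF exactly 10% kept
        (make_call(tt=20, ta=1), FATE_TUMOUR_VAF),        # 5% < 10%
        (make_call(nt=100, na=2), KEPT),                  # normal VAF exactly 2% kept
        (make_call(nt=100, na=3), FATE_NORMAL_VAF),       # 3% > 2%
        (make_call(snp=True), FATE_SNP),
    ])
    def test_boundary_conventions(self, call, expected_fate):
        kept, fates = sample_level_filter([call])
        assert fates[call.key] == expected_fate
        assert (call in kept) == (expected_fate == KEPT)

    def test_toy_list_one_failure_per_rule(self):
        calls = [
            make_call(pos=1, tt=10, ta=5),             # tumour depth
            make_call(pos=2, nt=5),                    # normal depth
            make_call(pos=3, tt=50, ta=2),             # tumour VAF 4%
            make_call(pos=4, nt=50, na=5),             # normal VAF 10%
            make_call(pos=5, snp=True),                # SNP site
            make_call(pos=6),                          # passes everything
        ]
        kept, fates = sample_level_filter(calls)
        assert [c.pos for c in kept] == [6]
        assert len(fates) == 6
        assert sorted(f for f in fates.values() if f != KEPT) == sorted([
            FATE_TUMOUR_DEPTH, FATE_NORMAL_DEPTH, FATE_TUMOUR_VAF,
            FATE_NORMAL_VAF, FATE_SNP,
        ])

    def test_zero_tumour_depth_fails_depth_rule_not_division(self):
        c = VariantCall("T1", "chr1", 1, "C", "T", 0, 0, 40, 0)
        _, fates = sample_level_filter([c])
        assert fates[c.key] == FATE_TUMOUR_DEPTH


class TestBackgroundBinomial:
    def test_zero_background_gives_zero_pvalue(self):
        assert background_binomial_pvalue(5, 30, 0, 0) == 0.0
        assert background_binomial_pvalue(5, 30, 0, 50_000) == 0.0

    def test_half_probability_enumeration(self):
        # X ~ Binomial(3, 0.5): P(X >= 2) = (3 + 1) / 8
        assert background_binomial_pvalue(2, 3, 1, 2) == pytest.approx(0.5)

    def test_moderate_background_value(self):
        # P(X >= 3), X ~ Binomial(30, 0.05): exact sum = 0.18782...
        p = background_binomial_pvalue(3, 30, 5, 100)
        expected = sum(
            math.comb(30, k) * 0.05**k * 0.95 ** (30 - k) for k in range(3, 31)
        )
        assert p == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(0.1878, abs=5e-4)

    def test_alt_exceeding_depth_rejected(self):
        with pytest.raises(ValueError):
            background_binomial_pvalue(10, 5, 0, 100)

    @given(n=st.integers(1, 12), alt=st.data(),
           num=st.integers(0, 20), extra=st.integers(1, 50))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_exhaustive_enumeration_small_depth(self, n, alt, num, extra):
        den = num + extra
        k = alt.draw(st.integers(0, n))
        p_bg = num / den
        expected = sum(
            math.comb(n, j) * p_bg**j * (1 - p_bg) ** (n - j) for j in range(k, n + 1)
        )
        assert background_binomial_pvalue(k, n, num, den) == pytest.approx(
            expected, abs=1e-12
        )


def _matrix(alt, total, samples, patients, called=None, unstable=None, types=None):
    alt = np.asarray(alt)
    variants = [("chr1", 100 + i, "C", "T") for i in range(alt.shape[0])]
    return CrossSampleReadMatrix(
        variants=variants,
        samples=samples,
        patient_of=dict(zip(samples, patients)),
        alt_reads=alt,
        total_reads=np.asarray(total),
        called=np.zeros_like(alt, dtype=bool) if called is None else np.asarray(called),
        unstable=unstable,
        sample_type=types or {},
    )


class TestDatasetLevelFilter:
    samples = ["T1", "N1", "T2", "N2"]
    patients = ["P1", "P1", "P2", "P2"]

    def test_zero_background_kept(self):
        m = _matrix([[10, 0, 0, 0]], [[30, 30, 25_000, 25_000]],
                    self.samples, self.patients)
        call = make_call(sample="T1", tt=30, ta=10)
        kept, fates = dataset_level_filter([call], m)
        assert fates[call.key] == KEPT and kept == [call]

    def test_uncalled_other_patient_high_vaf_discarded(self):
        m = _matrix([[10, 0, 4, 0]], [[30, 30, 20, 30]],
                    self.samples, self.patients)  # 4/20 = 20% in P2 tumour
        call = make_call(sample="T1", tt=30, ta=10)
        _, fates = dataset_level_filter([call], m)
        assert fates[call.key] == FATE_OTHER_PATIENT_VAF

    def test_called_other_patient_high_vaf_not_rule_b(self):
        called = [[True, False, True, False]]
        m = _matrix([[10, 0, 4, 0]], [[30, 30, 20, 30]],
                    self.samples, self.patients, called=called)
        call = make_call(sample="T1", tt=30, ta=10)
        _, fates = dataset_level_filter([call], m)
        # called in the other sample, so rule (b) passes; background 4/50 -> rule (c)
        assert fates[call.key] == FATE_BACKGROUND

    def test_background_binomial_discards(self):
        # caller 4/30; pooled other-patient background 500/10,000 (5%) -> p ~ 0.061
        m = _matrix([[4, 0, 250, 250]], [[30, 30, 5000, 5000]],
                    self.samples, self.patients)
        call = make_call(sample="T1", tt=30, ta=4)
        _, fates = dataset_level_filter([call], m)
        assert fates[call.key] == FATE_BACKGROUND
        p = background_binomial_pvalue(4, 30, 500, 10_000)
        assert p == pytest.approx(0.0608, abs=5e-4)

    def test_unstable_majority_discards(self):
        unstable = np.array([[True, True, True, False]])
        m = _matrix([[10, 0, 0, 0]], [[30, 30, 30, 30]],
                    self.samples, self.patients, unstable=unstable)
        call = make_call(sample="T1", tt=30, ta=10)
        _, fates = dataset_level_filter([call], m)
        assert fates[call.key] == "unstable_site"

    def test_missing_site_is_structural_error(self):
        m = _matrix([[10, 0, 0, 0]], [[30, 30, 30, 30]],
                    self.samples, self.patients)
        stray = make_call(sample="T1", pos=999, tt=30, ta=10)
        with pytest.raises(KeyError):
            dataset_level_filter([stray], m)


class TestPipelineLevelFilter:
    def test_idempotent_on_identical_lists(self):
        calls = [make_call(pos=p) for p in (1, 2, 3)]
        assert pipeline_level_filter(calls, list(calls)) == calls

    def test_disjoint_lists_empty(self):
        a = [make_call(pos=1)]
        b = [make_call(pos=2)]
        assert pipeline_level_filter(a, b) == []

    def test_partial_overlap_keeps_exactly_shared_keys(self):
        a = [make_call(pos=p) for p in (1, 2, 3, 4, 5)]
        b = [make_call(pos=p, tt=50, ta=20) for p in (2, 4, 5, 7)]
        kept = pipeline_level_filter(a, b)
        assert [c.pos for c in kept] == [2, 4, 5]
        assert all(c.tumour_total == 40 for c in kept)  # counts from list a


class TestRunCascade:
    def test_empty_input(self):
        m = _matrix(np.zeros((1, 2), int), np.ones((1, 2), int) * 30,
                    ["T1", "N1"], ["P1", "P1"])
        final, report = run_cascade([], [], m)
        assert final == []
        assert (report.n_input, report.n_after_pipeline) == (0, 0)

    def test_true_variants_survive_snps_do_not(self, rng):
        """100 clonal somatic variants at VAF 0.4 survive; flagged SNPs never do."""
        samples = ["T1", "N1", "T2", "N2"]
        patients = ["P1", "P1", "P2", "P2"]
        n = 200
        total = rng.poisson(38, size=(n, 4))
        alt = np.zeros_like(total)
        calls = []
        for i in range(n):
            is_snp = i >= 100
            total[i, 0] = max(total[i, 0], 20)
            alt[i, 0] = rng.binomial(total[i, 0], 0.4)
            if is_snp:
                alt[i, 1] = rng.binomial(total[i, 1], 0.5)
            calls.append(VariantCall(
                "T1", "chr1", 100 + i, "C", "T",
                int(total[i, 0]), int(alt[i, 0]),
                int(max(total[i, 1], 1)), int(min(alt[i, 1], total[i, 1])),
                is_snp_site=is_snp,
            ))
        variants = [("chr1", 100 + i, "C", "T") for i in range(n)]
        called = np.zeros((n, 4), bool)
        called[:, 0] = True
        m = CrossSampleReadMatrix(variants, samples, dict(zip(samples, patients)),
                                  alt, total, called)
        final, report = run_cascade(calls, calls, m)
        kept_snv = [c for c in final if not c.is_snp_site]
        assert len(kept_snv) >= 95
        assert not any(c.is_snp_site for c in final)
        report.validate()

    def test_error_only_comparison_monotone_ledger(self):
        calls_a, calls_b, m = simulate_normal_comparison(seed=5, n_sites=600)
        final, report = run_cascade(calls_a, calls_b, m)
        ledger = [report.n_input, report.n_after_sample,
                  report.n_after_dataset, report.n_after_pipeline]
        assert ledger == sorted(ledger, reverse=True)
        final_keys = {c.key for c in final}
        assert final_keys <= {c.key for c in calls_a}


class TestCohortCascade:
    def test_somatic_recall_and_snp_exclusion(self, cohort, cascade_result):
        final, report, _ = cascade_result
        report.validate()
        truth = cohort.truth
        kept_sites = {c.site for c in final}
        assert not any(truth[s] == "germline_snp" for s in kept_sites)
        # recall of clonal somatic variants at adequate depth and VAF
        eligible = {
            c.site for c in cohort.calls
            if truth[c.site] == "somatic_private"
            and c.tumour_total >= 30 and c.tumour_vaf >= 0.2
        }
        recall = len(eligible & kept_sites) / len(eligible)
        assert recall > 0.9

    def test_error_sites_nearly_all_removed(self, cohort, cascade_result):
        final, _, _ = cascade_result
        n_err_kept = sum(
            1 for c in final if cohort.truth[c.site] == SEQUENCING_ERROR
        )
        n_err = sum(1 for v in cohort.truth.values() if v == SEQUENCING_ERROR)
        assert n_err > 0 and n_err_kept / n_err < 0.1
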