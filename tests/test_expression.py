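"""Overexpression calling: transforms, thresholds, call rates, recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from immunocall import (
    ExpressionCohort,
    ExpressionSimConfig,
    GeneSpec,
    call_overexpression,
    compute_thresholds,
    gen_expression_cohort,
    recover_activation,
    threshold_tissue_restricted,
    threshold_ubiquitous,
    transform_expression,
)


def _cohort_from_matrix(values, groups, subtypes, platform="microarray_rma",
                        gene_classes=None):
    samples = pd.DataFrame(
        {"group": groups, "subtype": subtypes, "platform": platform},
        index=pd.Index(list(values.columns), name="sample_id"),
    )
    genes = pd.DataFrame(
        {"gene_class": gene_classes or ["tissue_restricted"] * len(values.index)},
        index=pd.Index(list(values.index), name="gene_id"),
    )
    return ExpressionCohort(values=values, samples=samples, genes=genes)


class TestTransform:
    @pytest.mark.parametrize("fpkm,expected", [(0.0, 0.0), (1.0, 1.0), (7.0, 3.0)])
    def test_log2_1p_on_fpkm(self, fpkm, expected):
        values = pd.DataFrame({"s1": [fpkm]}, index=["g"])
        cohort = _cohort_from_matrix(values, ["tumor"], ["AC"], platform="rnaseq_fpkm")
        assert transform_expression(cohort).loc["g", "s1"] == pytest.approx(expected)

    def test_microarray_passthrough_when_already_log2(self):
        values = pd.DataFrame({"s1": [5.5], "s2": [8.0]}, index=["g"])
        cohort = _cohort_from_matrix(values, ["normal", "tumor"], ["NA", "AC"])
        pd.testing.assert_frame_equal(transform_expression(cohort), values.astype(float))

    def test_microarray_log2_applied_when_flagged_linear(self):
        values = pd.DataFrame({"s1": [8.0]}, index=["g"])
        cohort = _cohort_from_matrix(values, ["tumor"], ["AC"])
        out = transform_expression(cohort, microarray_already_log2=False)
        assert out.loc["g", "s1"] == pytest.approx(3.0)

    def test_negative_fpkm_rejected(self):
        values = pd.DataFrame({"s1": [-1.0]}, index=["g"])
        with pytest.raises(ValueError):
            _cohort_from_matrix(values, ["tumor"], ["AC"], platform="rnaseq_fpkm")


class TestThresholds:
    def test_zero_sd_threshold_equals_mean(self):
        assert threshold_tissue_restricted([5, 5, 5, 5], 2).threshold == pytest.approx(5.0)
        assert threshold_ubiquitous([1, 1, 1, 1], 2).threshold == pytest.approx(1.0)

    def test_mean_plus_two_sample_sd(self):
        # mean 2, sample SD 1 (n-1 denominator) -> 4
        thr = threshold_tissue_restricted([1, 2, 3], 2)
        assert thr.threshold == pytest.approx(4.0)
        assert thr.regime == "normal_mean_plus_2sd"
        assert thr.n_reference_samples == 3

    def test_all_zero_reference_panel(self):
        thr = threshold_ubiquitous([0, 0, 0], 2)
        assert thr.threshold == pytest.approx(0.0)
        assert thr.regime == "fixed_reference_calibrated"

    def test_monte_carlo_threshold_converges(self):
        rng = np.random.default_rng(0)
        n = 10_000
        thr = threshold_tissue_restricted(rng.normal(3.0, 0.5, n), 2).threshold
        se = 0.5 * math.sqrt(1 / n + 4 / (2 * (n - 1)))
        assert abs(thr - 4.0) < 3 * se

    def test_monte_carlo_reference_threshold(self):
        rng = np.random.default_rng(1)
        thr = threshold_ubiquitous(rng.normal(1.0, 0.2, 100), 2).threshold
        se = 0.2 * math.sqrt(1 / 100 + 4 / (2 * 99))
        assert abs(thr - 1.4) < 3 * se

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            threshold_tissue_restricted([5.0], 2)
        with pytest.raises(ValueError):
            threshold_ubiquitous([], 2)


class TestCallOverexpression:
    def _simple_cohort(self, tumor_values, normal_values=(1.0, 2.0, 3.0)):
        cols = [f"n{i}" for i in range(len(normal_values))] + [
            f"t{i}" for i in range(len(tumor_values))
        ]
        values = pd.DataFrame([list(normal_values) + list(tumor_values)],
                              index=["g"], columns=cols)
        groups = ["normal"] * len(normal_values) + ["tumor"] * len(tumor_values)
        subtypes = ["NA"] * len(normal_values) + ["AC"] * len(tumor_values)
        return _cohort_from_matrix(values, groups, subtypes)

    def test_counts_strictly_above_threshold(self):
        cohort = self._simple_cohort([4.5, 5.5, 6.0])
        logm = transform_expression(cohort)
        thr = compute_thresholds(logm, cohort)  # normals [1,2,3] -> threshold 4
        # override to the worked threshold of 5
        from immunocall.types import GeneThreshold
        thr = {"g": GeneThreshold("g", 5.0, "normal_mean_plus_2sd", 3)}
        summary = call_overexpression(logm, thr, cohort)
        rec = summary.iloc[0]
        assert (rec["n_above"], rec["n_tumors"]) == (2, 3)
        assert rec["percent"] == pytest.approx(66.6667, abs=1e-3)

    def test_tie_at_threshold_not_called(self):
        cohort = self._simple_cohort([4.0, 3.9])  # threshold is exactly 4
        logm = transform_expression(cohort)
        summary = call_overexpression(logm, compute_thresholds(logm, cohort), cohort)
        assert summary.iloc[0]["n_above"] == 0

    def test_all_below_threshold_is_zero_percent(self):
        cohort = self._simple_cohort([0.5, 1.0, 2.0])
        logm = transform_expression(cohort)
        summary = call_overexpression(logm, compute_thresholds(logm, cohort), cohort)
        assert summary.iloc[0]["percent"] == 0.0

    def test_missing_values_excluded_from_both_counts(self):
        cohort = self._simple_cohort([5.0, np.nan, 6.0])
        logm = transform_expression(cohort)
        summary = call_overexpression(logm, compute_thresholds(logm, cohort), cohort)
        assert summary.iloc[0]["n_tumors"] == 2 and summary.iloc[0]["n_above"] == 2

    def test_subtype_without_tumors_reported_not_applicable(self):
        cohort = self._simple_cohort([5.0])
        logm = transform_expression(cohort)
        summary = call_overexpression(
            logm, compute_thresholds(logm, cohort), cohort, subtypes=["AC", "SCC"]
        )
        scc = summary[summary["subtype"] == "SCC"].iloc[0]
        assert scc["n_tumors"] == 0 and math.isnan(scc["percent"])

    def test_missing_threshold_raises(self):
        cohort = self._simple_cohort([5.0])
        logm = transform_expression(cohort)
        with pytest.raises(KeyError):
            call_overexpression(logm, {}, cohort)

    def test_percent_nonincreasing_in_sd_multiplier(self, small_expression_cohort):
        _, cohort, _ = small_expression_cohort
        logm = transform_expression(cohort)
        previous = None
        for k in (0.5, 1.0, 2.0, 3.0, 4.0):
            summary = call_overexpression(logm, compute_thresholds(logm, cohort, k), cohort)
            percents = summary["percent"].to_numpy()
            if previous is not None:
                assert (percents <= previous + 1e-12).all()
            previous = percents

    def test_calling_scale_consistency_fpkm_vs_prelog(self):
        # calling on linear FPKM equals calling on pre-transformed log2(1+FPKM)
        spec = GeneSpec("G1", "tissue_restricted", {"AC": 0.4})
        cfg = ExpressionSimConfig(genes=(spec,), n_normal=20,
                                  n_tumor_per_subtype={"AC": 50}, n_reference=0,
                                  platform="rnaseq_fpkm", seed=21)
        cohort, _ = gen_expression_cohort(cfg)
        logm = transform_expression(cohort)
        pre = ExpressionCohort(
            values=logm,
            samples=cohort.samples.assign(platform="microarray_rma"),
            genes=cohort.genes,
        )
        logm2 = transform_expression(pre)
        s1 = call_overexpression(logm, compute_thresholds(logm, cohort), cohort)
        s2 = call_overexpression(logm2, compute_thresholds(logm2, pre), pre)
        pd.testing.assert_frame_equal(s1, s2)


class TestNullCalibration:
    def test_iid_tumors_called_at_gaussian_tail_mass(self):
        # tumors drawn from the normal background: expected call rate is
        # the upper tail beyond 2 SD, 1 - Phi(2) = 2.275%
        spec = GeneSpec("G1", "tissue_restricted", {"AC": 0.0},
                        background_mean=5.0, background_sd=0.5)
        cfg = ExpressionSimConfig(genes=(spec,), n_normal=10_000,
                                  n_tumor_per_subtype={"AC": 10_000},
                                  n_reference=0, seed=17)
        cohort, _ = gen_expression_cohort(cfg)
        logm = transform_expression(cohort)
        summary = call_overexpression(logm, compute_thresholds(logm, cohort), cohort)
        assert summary.iloc[0]["percent"] == pytest.approx(2.275, abs=0.5)


class TestOracleEquivalence:
    @staticmethod
    def _brute_force(logm, thresholds, cohort, subtypes):
        rows = []
        ann = cohort.samples
        for gene in logm.index:
            t = thresholds[gene].threshold
            for sub in subtypes:
                n = above = 0
                for sample in logm.columns:
                    if ann.loc[sample, "group"] != "tumor" or ann.loc[sample, "subtype"] != sub:
                        continue
                    v = logm.loc[gene, sample]
                    if math.isnan(v):
                        continue
                    n += 1
                    if v > t:
                        above += 1
                rows.append((gene, sub, n, above))
        return rows

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        n_genes=st.integers(1, 10),
        n_tumor=st.integers(1, 16),
        data=st.data(),
    )
    def test_call_counts_match_double_loop(self, n_genes, n_tumor, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        n_normal = 4
        cols = [f"n{i}" for i in range(n_normal)] + [f"t{i}" for i in range(n_tumor)]
        values = pd.DataFrame(
            rng.normal(5, 2, size=(n_genes, n_normal + n_tumor)),
            index=[f"g{i}" for i in range(n_genes)], columns=cols,
        )
        subtypes = ["NA"] * n_normal + [
            data.draw(st.sampled_from(["AC", "SCC"])) for _ in range(n_tumor)
        ]
        cohort = _cohort_from_matrix(
            values, ["normal"] * n_normal + ["tumor"] * n_tumor, subtypes
        )
        logm = transform_expression(cohort)
        thresholds = compute_thresholds(logm, cohort)
        summary = call_overexpression(logm, thresholds, cohort, subtypes=["AC", "SCC"])
        expected = self._brute_force(logm, thresholds, cohort, ["AC", "SCC"])
        got = list(summary[["gene_id", "subtype", "n_tumors", "n_above"]].itertuples(index=False, name=None))
        assert got == expected


class TestRecovery:
    def test_extreme_fractions_behave_as_planted(self):
        # fraction 0 with a huge shift: only tail-mass false positives;
        # fraction 1: nearly every tumor called
        for frac, check in ((0.0, lambda p: p <= 6.0), (1.0, lambda p: p >= 99.0)):
            spec = GeneSpec("G1", "tissue_restricted", {"AC": frac},
                            background_sd=0.5, activation_shift=5.0)
            cfg = ExpressionSimConfig(genes=(spec,), n_normal=50,
                                      n_tumor_per_subtype={"AC": 200},
                                      n_reference=0, seed=23)
            cohort, truth = gen_expression_cohort(cfg)
            logm = transform_expression(cohort)
            thr = compute_thresholds(logm, cohort)
            summary = call_overexpression(logm, thr, cohort)
            assert check(summary.iloc[0]["percent"])

    def test_recovery_report_covers_planted_mixture(self):
        # planted 0.4 at 4-SD shift: called percent tracks the mixture
        # expectation 0.4 * P(detect | activated) + 0.6 * tail mass
        spec = GeneSpec("G1", "tissue_restricted", {"AC": 0.4},
                        background_sd=0.5, activation_shift=2.0)
        cfg = ExpressionSimConfig(genes=(spec,), n_normal=50,
                                  n_tumor_per_subtype={"AC": 200},
                                  n_reference=0, seed=1)
        cohort, truth = gen_expression_cohort(cfg)
        logm = transform_expression(cohort)
        thr = compute_thresholds(logm, cohort)
        summary = call_overexpression(logm, thr, cohort)
        report = recover_activation(summary, truth, thr)
        rec = report.iloc[0]
        assert rec["planted_fraction"] == 0.4
        assert rec["covered_95"]
        assert abs(rec["called_percent"] - rec["expected_percent"]) < 10.0

    def test_key_mismatch_raises(self, small_expression_cohort):
        _, cohort, truth = small_expression_cohort
        logm = transform_expression(cohort)
        thr = compute_thresholds(logm, cohort)
        summary = call_overexpression(logm, thr, cohort)
        bad = summary.copy()
        bad.loc[0, "gene_id"] = "NOPE"
        with pytest.raises(KeyError):
            recover_activation(bad, truth, thr)
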