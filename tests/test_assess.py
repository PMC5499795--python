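"""Confusion metrics, ROC/AUC, cut-off optimization, residue overlap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbdkit.assess import (ConfusionCounts, metrics, optimize_cutoff,
                           residue_overlap, roc, round_half_up)
from rbdkit.errors import DegenerateLabelsError

from oracles import ranksum_auc


class TestMetrics:
    def test_kinase_cohort_sensitivity(self):
        # 106 of 110 reference kinases recovered
        m = metrics(ConfusionCounts(tp=106, fp=0, tn=0, fn=4))
        assert round_half_up(m.sn) == 0.96

    def test_proteome_rbp_sensitivity(self):
        # 1091 of 1535 reference RBPs recovered
        m = metrics(ConfusionCounts(tp=1091, fp=0, tn=0, fn=444))
        assert round_half_up(m.sn) == 0.71

    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(tp=10, fp=0, tn=20, fn=0))
        assert (m.sn, m.sp, m.acc, m.mcc, m.fmeasure) == (1, 1, 1, 1, 1)

    def test_mcc_direct_formula(self):
        m = metrics(ConfusionCounts(tp=5, fp=1, tn=4, fn=2))
        assert m.mcc == pytest.approx(18 / math.sqrt(1260))

    def test_fmeasure_uses_sn_and_sp(self):
        c = ConfusionCounts(tp=8, fp=4, tn=6, fn=2)
        m = metrics(c)
        assert m.fmeasure == pytest.approx(2 * m.sn * m.sp / (m.sn + m.sp))

    def test_zero_denominators_define_metric_as_zero(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, tn=0, fn=0))
        assert (m.sn, m.sp, m.acc, m.mcc, m.fmeasure) == (0, 0, 0, 0, 0)
        m = metrics(ConfusionCounts(tp=3, fp=0, tn=0, fn=0))
        assert m.sp == 0 and m.mcc == 0

    @settings(max_examples=50, deadline=None)
    @given(tp=st.integers(0, 50), fp=st.integers(0, 50),
           tn=st.integers(0, 50), fn=st.integers(0, 50),
           k=st.integers(2, 9))
    def test_scale_invariance(self, tp, fp, tn, fn, k):
        m1 = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        m2 = metrics(ConfusionCounts(tp=k * tp, fp=k * fp, tn=k * tn,
                                     fn=k * fn))
        for field in ("sn", "sp", "acc", "mcc", "fmeasure"):
            assert getattr(m1, field) == pytest.approx(getattr(m2, field))


class TestRoc:
    def test_perfect_separation(self):
        curve = roc([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert curve.auc == pytest.approx(1.0)

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=2000)
        labels = rng.random(2000) < 0.5
        assert roc(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_four_point_toy_matches_ranksum(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [False, True, False, True]
        assert roc(scores, labels).auc == pytest.approx(
            ranksum_auc(scores, labels))

    @settings(max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_random_instances_match_ranksum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        # coarse grid makes score ties common, exercising tie grouping
        scores = rng.integers(0, 6, size=n).astype(float)
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        assert roc(scores, labels).auc == pytest.approx(
            ranksum_auc(scores, labels))

    def test_endpoints_and_ordering(self):
        curve = roc([0.2, 0.6, 0.4, 0.9], [False, True, False, True])
        fprs = [p[0] for p in curve.points]
        assert fprs == sorted(fprs)
        assert (curve.points[0][0], curve.points[0][1]) == (0.0, 0.0)
        assert (curve.points[-1][0], curve.points[-1][1]) == (1.0, 1.0)

    def test_single_class_is_degenerate(self):
        with pytest.raises(DegenerateLabelsError):
            roc([0.1, 0.2], [True, True])


class TestOptimizeCutoff:
    def test_separable_case_picks_least_stringent_perfect_threshold(self):
        values = [40.0, 45.0, 50.0, 20.0, 30.0, 34.9]
        labels = [True, True, True, False, False, False]
        result = optimize_cutoff(values, labels, direction="min-threshold")
        assert result.metrics.acc == 1.0
        assert result.threshold == 40.0  # smallest swept value above the negatives

    def test_max_threshold_direction(self):
        values = [1e-9, 1e-7, 0.5, 2.0]
        labels = [True, True, False, False]
        result = optimize_cutoff(values, labels, direction="max-threshold")
        assert result.metrics.acc == 1.0
        assert result.threshold == pytest.approx(1e-7)

    def test_bimodal_recovery_with_contamination(self):
        rng = np.random.default_rng(23)
        pos = rng.normal(70, 5, 100)
        neg = rng.normal(20, 5, 100)
        # 10% contamination: swap tails across the classes
        pos[:10] = rng.normal(20, 5, 10)
        neg[:10] = rng.normal(70, 5, 10)
        values = np.concatenate([pos, neg])
        labels = [True] * 100 + [False] * 100
        result = optimize_cutoff(values, labels)
        assert 30 < result.threshold < 60
        assert result.metrics.acc >= 0.9

    def test_sweep_rows_match_independent_recomputation(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 100, 30)
        labels = rng.random(30) < 0.4
        labels[0], labels[1] = True, False
        result = optimize_cutoff(values, labels)
        for row in result.sweep[::5]:
            t = row["threshold"]
            tp = sum(1 for v, l in zip(values, labels) if v >= t and l)
            fp = sum(1 for v, l in zip(values, labels) if v >= t and not l)
            tn = sum(1 for v, l in zip(values, labels) if v < t and not l)
            fn = sum(1 for v, l in zip(values, labels) if v < t and l)
            m = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            assert row["metrics"] == m

    def test_chosen_accuracy_dominates_sweep(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(0, 1, 40)
        labels = values + rng.normal(0, 0.3, 40) > 0.5
        labels[0], labels[1] = True, False
        result = optimize_cutoff(values, labels)
        assert all(result.metrics.acc >= row["metrics"].acc
                   for row in result.sweep)


class TestResidueOverlap:
    def test_partial_overlap_fraction(self):
        report = residue_overlap({"p": [(1, 10)]}, {"p": [5, 10, 20]})
        assert report.per_protein["p"] == pytest.approx(2 / 3)
        assert report.recovered["p"]

    def test_full_overlap(self):
        report = residue_overlap({"p": [(1, 30)]}, {"p": [2, 15, 30]})
        assert report.per_protein["p"] == 1.0

    def test_no_intervals_means_not_recovered(self):
        report = residue_overlap({}, {"p": [4, 7]})
        assert report.per_protein["p"] == 0.0
        assert not report.recovered["p"]
        assert report.sensitivity == 0.0

    def test_cohort_sensitivity_and_high_overlap_count(self):
        intervals = {"a": [(1, 50)], "b": [(1, 5)], "c": []}
        residues = {"a": [1, 2, 3], "b": [4, 90, 91, 92], "c": [8]}
        report = residue_overlap(intervals, residues)
        assert report.sensitivity == pytest.approx(2 / 3)
        assert report.n_high_overlap == 1  # only "a" exceeds 70%

    def test_protein_without_residues_excluded(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            report = residue_overlap({"p": [(1, 5)]}, {"p": [], "q": [2]})
        assert report.excluded == ["p"]
        assert "q" in report.per_protein
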