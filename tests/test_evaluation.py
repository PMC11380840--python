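import random

import pytest
from hypothesis import given, settings, strategies as st

from netprio import (
    OverlapResult, build_all_lists, build_all_smv, build_universe,
    evaluate_run, overlap, roc_from_cutoffs,
)


class TestOverlap:
    def test_direct_counts(self):
        universe = {f"u{i}" for i in range(90)} | {f"p{i}" for i in range(10)}
        predicted = [f"p{i}" for i in range(10)]
        validation = {"p0", "p1", "u0", "u1", "u2"}
        res = overlap(predicted, validation, universe)
        assert (res.tp, res.fp, res.fn, res.tn) == (2, 8, 3, 87)
        assert res.precision == pytest.approx(0.2)
        assert res.recall == pytest.approx(0.4)
        assert res.f_measure == pytest.approx(0.26667, abs=1e-4)

    def test_identity_case(self):
        genes = {"a", "b", "c"}
        res = overlap(sorted(genes), genes, genes)
        assert res.precision == res.recall == res.f_measure == 1.0

    def test_disjoint_case(self):
        res = overlap(["a"], {"b"}, {"a", "b"})
        assert res.precision == res.recall == res.f_measure == 0.0

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="empty universe"):
            overlap([], set(), set())

    def test_unreachable_validation_genes(self):
        res = overlap(["a"], {"a", "zzz"}, {"a", "b"})
        assert res.unreachable == 1 and res.fn == 0
        strict = overlap(["a"], {"a", "zzz"}, {"a", "b"}, strict=True)
        assert strict.fn == 1

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50))
    def test_metric_identities(self, tp, fp, fn, tn):
        """P, R, F follow their defining ratios; F is the harmonic mean,
        bounded by min/max of P and R, zero iff P·R = 0."""
        res = OverlapResult(tp=tp, fp=fp, fn=fn, tn=tn)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        assert res.precision == pytest.approx(p)
        assert res.recall == pytest.approx(r)
        assert res.f_measure == pytest.approx(f)
        assert min(p, r) - 1e-12 <= res.f_measure <= max(p, r) + 1e-12
        assert (res.f_measure == 0.0) == (p * r == 0.0)


class TestROC:
    def interior(self, tp, fn, fp, tn):
        return OverlapResult(tp=tp, fp=fp, fn=fn, tn=tn)

    def test_single_point_trapezoid_by_hand(self):
        # FPR=0.1, TPR=0.4 -> 0.5·0.1·0.4 + 0.9·(0.4+1)/2 = 0.65
        res = self.interior(tp=4, fn=6, fp=10, tn=90)
        curve = roc_from_cutoffs([res])
        assert curve.auc == pytest.approx(0.65)
        assert curve.points[0] == (0.0, 0.0) and curve.points[-1] == (1.0, 1.0)

    def test_perfect_classifier(self):
        curve = roc_from_cutoffs([self.interior(tp=5, fn=0, fp=0, tn=5)])
        assert curve.auc == pytest.approx(1.0)

    def test_chance_line(self):
        curve = roc_from_cutoffs([self.interior(tp=3, fn=7, fp=3, tn=7)])
        assert curve.auc == pytest.approx(0.5)

    def test_degenerate_classes_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            roc_from_cutoffs([self.interior(tp=0, fn=0, fp=1, tn=1)])

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_single_point_closed_form(self, fpr, tpr):
        """AUC of one interior point matches the closed-form triangle +
        trapezoid decomposition."""
        tp, fn = int(round(tpr * 1000)), 1000 - int(round(tpr * 1000))
        fp, tn = int(round(fpr * 1000)), 1000 - int(round(fpr * 1000))
        if tp + fn == 0 or fp + tn == 0:
            return
        res = OverlapResult(tp=tp, fp=fp, fn=fn, tn=tn)
        expected = 0.5 * res.fpr * res.tpr + (1 - res.fpr) * (res.tpr + 1) / 2
        assert roc_from_cutoffs([res]).auc == pytest.approx(expected)

    def test_monotone_counts_across_nested_cutoffs(self, small_bundle):
        net = small_bundle.network
        d = next(iter(small_bundle.seed_sets))
        seeds = small_bundle.seed_sets[d]
        val = small_bundle.validations[d]
        lists = build_all_lists(net, [seeds], ["AA"], [10, 50, 100])
        uni = build_universe(net, seeds, val)
        results = [overlap(l.symbols, val, uni) for l in lists]
        for prev, nxt in zip(results, results[1:]):
            assert nxt.tp >= prev.tp and nxt.fp >= prev.fp


class TestEvaluateRun:
    def run_tables(self, bundle, indices=("PAC", "AA", "JC", "RAI"),
                   ks=(10, 50, 100)):
        net = bundle.network
        seeds = list(bundle.seed_sets.values())
        ranked = build_all_lists(net, seeds, list(indices), list(ks))
        smv = build_all_smv(ranked)
        return evaluate_run(ranked, smv, bundle.validations, net,
                            bundle.seed_sets)

    def test_table_shape_and_flags(self, small_bundle):
        ev = self.run_tables(small_bundle)
        n_diseases = len(small_bundle.seed_sets)
        assert len(ev.metrics) == n_diseases * 5 * 3  # 4 indices + SMV
        assert set(ev.metrics["method"]) == {"PAC", "AA", "JC", "RAI", "SMV"}
        # SB/SW flagged among the index rows of every (disease, k)
        lsi = ev.metrics[ev.metrics["method"] != "SMV"]
        for _, grp in lsi.groupby(["disease", "k"]):
            assert grp["single_best"].any() and grp["single_worst"].any()
        assert not ev.metrics[ev.metrics["method"] == "SMV"]["single_best"].any()

    def test_confusion_sums_to_universe(self, small_bundle):
        ev = self.run_tables(small_bundle)
        net = small_bundle.network
        for _, row in ev.metrics.iterrows():
            seeds = small_bundle.seed_sets[row["disease"]]
            uni = build_universe(net, seeds,
                                 small_bundle.validations[row["disease"]])
            assert row["tp"] + row["fp"] + row["fn"] + row["tn"] == len(uni)

    def test_smv_f_tracks_single_worst_to_best_band(self, small_bundle):
        """On planted-module data the ensemble F-measure stays in the
        single-worst..single-best band on average per disease (the
        per-cutoff value can dip marginally below the worst index since
        the ensemble list length is set by votes, not by k)."""
        ev = self.run_tables(small_bundle)
        for d, grp in ev.metrics.groupby("disease"):
            lsi = grp[grp["method"] != "SMV"]
            sw = lsi.groupby("k")["f_measure"].min().mean()
            sb = lsi.groupby("k")["f_measure"].max().mean()
            smv_f = grp[grp["method"] == "SMV"]["f_measure"].mean()
            assert smv_f >= sw - 1e-12, d
            assert smv_f <= sb + 0.1, d  # may exceed SB, never wildly

    def test_missing_validation_errors(self, small_bundle):
        net = small_bundle.network
        seeds = list(small_bundle.seed_sets.values())
        ranked = build_all_lists(net, seeds, ["AA"], [10])
        with pytest.raises(ValueError, match="missing validation"):
            evaluate_run(ranked, [], {}, net, small_bundle.seed_sets)

    def test_auc_rows_per_disease_method(self, small_bundle):
        ev = self.run_tables(small_bundle)
        assert len(ev.auc) == len(small_bundle.seed_sets) * 5
        assert ((ev.auc["auc"] >= 0) & (ev.auc["auc"] <= 1)).all()
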