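"""Pooled thresholds, ROC analysis and Kruskal-Wallis/Dunn statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bulbflow import stats
from bulbflow.errors import DegenerateLabelError, SizeError
from bulbflow.volumetric import MetricSummary


class TestPooledPercentile:
    def test_linear_interpolation_convention(self):
        vals = [np.arange(1.0, 101.0)]
        assert stats.pooled_percentile_threshold(vals, "upper", 1.0) == pytest.approx(99.01)

    def test_all_equal(self):
        assert stats.pooled_percentile_threshold([np.full(10, 3.3)], "lower", 1.0) == 3.3

    def test_lower_upper_symmetry(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        lo = stats.pooled_percentile_threshold([x], "lower", 1.0)
        hi = stats.pooled_percentile_threshold([-x], "upper", 1.0)
        assert lo == pytest.approx(-hi, rel=1e-12)

    def test_pools_across_subjects(self):
        a, b = np.arange(0.0, 50.0), np.arange(50.0, 100.0)
        both = stats.pooled_percentile_threshold([a, b], "upper", 10.0)
        assert both == pytest.approx(np.percentile(np.arange(100.0), 90))

    def test_empty_rejected(self):
        with pytest.raises(SizeError):
            stats.pooled_percentile_threshold([], "upper", 1.0)


class TestROC:
    def test_perfect_separation(self):
        r = stats.roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0 and r.gini == 1.0

    def test_all_tied_scores(self):
        r = stats.roc_curve([5, 5, 5, 5], [0, 1, 0, 1])
        assert r.auc == 0.5

    def test_concordant_pair_example(self):
        r = stats.roc_curve([2, 1, 3, 4], [1, 0, 0, 1])
        assert r.auc == pytest.approx(0.75)

    def test_auc_equals_trapezoid(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.4
        labels[0], labels[1] = True, False
        r = stats.roc_curve(scores, labels)
        assert r.auc == pytest.approx(r.auc_trapezoid, abs=1e-12)
        assert r.gini == pytest.approx(2 * r.auc - 1, abs=1e-15)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        scores = rng.normal(size=60) + np.repeat([0, 1], 30)
        labels = np.repeat([False, True], 30)
        r = stats.roc_curve(scores, labels)
        assert r.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelError):
            stats.roc_curve([1, 2, 3], [1, 1, 1])

    def test_curve_monotone(self):
        rng = np.random.default_rng(3)
        r = stats.roc_curve(rng.normal(size=30), rng.random(30) < 0.5)
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)
        assert (r.fpr[0], r.tpr[0]) == (0, 0) and (r.fpr[-1], r.tpr[-1]) == (1, 1)


class TestThresholdSweep:
    def test_single_candidate(self):
        best, res = stats.threshold_sweep({3.0: [1, 2, 3, 4]}, [0, 0, 1, 1])
        assert best == 3.0 and 3.0 in res

    def test_tie_goes_to_smallest(self):
        scores = {1.0: [1, 2, 3, 4], 5.0: [10, 20, 30, 40]}
        best, _ = stats.threshold_sweep(scores, [0, 0, 1, 1])
        assert best == 1.0

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        labels = np.repeat([0, 1], 10)
        cands = {c: rng.normal(size=20) + labels * c for c in (0.5, 3.0, 7.5)}
        b1, _ = stats.threshold_sweep(cands, labels)
        b2, _ = stats.threshold_sweep(dict(reversed(list(cands.items()))), labels)
        assert b1 == b2


class TestKruskalWallis:
    def test_hand_computed_h(self):
        comp = stats.kruskal_wallis_pairwise([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert comp.h_statistic == pytest.approx(7.2, abs=1e-12)

    def test_matches_scipy(self):
        from scipy.stats import kruskal

        rng = np.random.default_rng(5)
        groups = [rng.normal(loc=mu, size=n) for mu, n in ((0, 13), (1, 7), (0.5, 6))]
        comp = stats.kruskal_wallis_pairwise(groups)
        h, p = kruskal(*groups)
        assert comp.h_statistic == pytest.approx(h, rel=1e-12)
        assert comp.p_omnibus == pytest.approx(p, rel=1e-12)

    def test_identical_groups(self):
        comp = stats.kruskal_wallis_pairwise([[2, 2, 2], [2, 2, 2], [2, 2, 2]])
        assert comp.h_statistic == 0.0
        assert comp.p_omnibus == 1.0
        assert all(p == 1.0 for p in comp.pairwise_p.values())

    def test_permutation_p_matches_exhaustive_enumeration(self):
        """The Monte-Carlo permutation p-value agrees with brute-force
        enumeration over all group assignments on a tiny instance."""
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]]
        comp = stats.kruskal_wallis_pairwise(
            groups, p_method="permutation", n_permutations=40000, rng=0
        )
        pooled = frozenset([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        h_obs = comp.h_statistic
        count = total = 0
        for g1 in itertools.combinations(sorted(pooled), 3):
            rest = pooled - set(g1)
            for g2 in itertools.combinations(sorted(rest), 3):
                g3 = sorted(rest - set(g2))
                total += 1
                h = stats._kw_h([list(g1), list(g2), list(g3)])
                count += h >= h_obs - 1e-12
        p_exact = count / total
        # Monte-Carlo error ~ sqrt(p(1-p)/B)
        mc_err = 3 * np.sqrt(p_exact * (1 - p_exact) / 40000) + 1e-4
        assert comp.p_omnibus == pytest.approx(p_exact, abs=mc_err + 5e-4)

    def test_dunn_direction_and_adjustment(self):
        rng = np.random.default_rng(6)
        low = rng.normal(0, 1, 13)
        high = rng.normal(5, 1, 7)
        mid = rng.normal(2.5, 1, 6)
        comp = stats.kruskal_wallis_pairwise([low, high, mid],
                                             labels=["low", "high", "mid"])
        raw = stats.kruskal_wallis_pairwise([low, high, mid],
                                            labels=["low", "high", "mid"],
                                            adjust="none")
        assert comp.pairwise_p[("low", "high")] < 0.05
        for pair in comp.pairwise_p:
            assert comp.pairwise_p[pair] >= raw.pairwise_p[pair]

    def test_size_contracts(self):
        with pytest.raises(SizeError):
            stats.kruskal_wallis_pairwise([[1, 2, 3]])
        with pytest.raises(SizeError):
            stats.kruskal_wallis_pairwise([[1, 2], [3]])


class TestGroupSummary:
    def make_summaries(self):
        out = []
        data = {
            "caw": [100, 100, 95, 100, 90],
            "atherosclerosis": [55, 60, 50],
            "normal": [80, 75, 85],
        }
        for g, vals in data.items():
            for i, v in enumerate(vals):
                out.append(MetricSummary(
                    subject_id=f"{g}{i}", group_label=g, event_label=g == "caw",
                    stasis_pct=v, low_velocity_volume_pct=v / 10,
                ))
        return out

    def test_full_cycle_count(self):
        comps, full = stats.group_summary_table(self.make_summaries())
        assert full == {"caw": 3, "atherosclerosis": 0, "normal": 0}

    def test_single_group_no_pvalues(self):
        singles = [s for s in self.make_summaries() if s.group_label == "caw"]
        comps, _ = stats.group_summary_table(singles)
        assert comps["stasis_pct"].pairwise_p == {}

    def test_table_frame_shape(self):
        comps, full = stats.group_summary_table(self.make_summaries())
        df = stats.comparisons_to_frame(comps, full)
        assert "caw_mean" in df.columns
        assert (df["metric"] == "stasis_full_cycle_count").any()
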