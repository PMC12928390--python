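"""Confusion metrics, AUROC, drug filters, group tests and recurrence."""

import numpy as np
import pandas as pd
import pytest

from ktsp.core import KTSPResults, TSPRule
from ktsp.evaluation import (
    auroc,
    confusion_metrics,
    drug_inclusion_filter,
    gene_recurrence,
    rule_compliance_profile,
    sdss_group_test,
)


def brute_force_auroc(truth, scores):
    """Exhaustive cross-class pair counting, the independent oracle."""
    truth = np.asarray([t == "sensitive" if isinstance(t, str) else bool(t)
                        for t in truth])
    scores = np.asarray(scores, dtype=float)
    pos, neg = scores[truth], scores[~truth]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def bh_stepup(pvals):
    """Hand Benjamini–Hochberg step-up, the oracle for adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        r = confusion_metrics(["sensitive", "resistant"], ["sensitive", "resistant"])
        assert (r.sensitivity, r.specificity, r.balanced_accuracy) == (1.0, 1.0, 1.0)

    def test_majority_class_collapse_scores_half(self):
        truth = ["sensitive"] * 3 + ["resistant"] * 7
        pred = ["resistant"] * 10
        r = confusion_metrics(truth, pred)
        assert r.sensitivity == 0.0
        assert r.specificity == 1.0
        assert r.balanced_accuracy == 0.5

    def test_hand_confusion_arithmetic(self):
        truth = ["sensitive"] * 4 + ["resistant"] * 4
        pred = (["sensitive"] * 3 + ["resistant"]  # TP=3, FN=1
                + ["sensitive"] * 2 + ["resistant"] * 2)  # FP=2, TN=2
        r = confusion_metrics(truth, pred)
        assert (r.tp, r.fn, r.fp, r.tn) == (3, 1, 2, 2)
        assert r.sensitivity == 0.75
        assert r.specificity == 0.5
        assert r.balanced_accuracy == 0.625

    def test_absent_class_is_nan_not_zero(self):
        r = confusion_metrics(["resistant", "resistant"], ["resistant", "sensitive"])
        assert np.isnan(r.sensitivity)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(["sensitive"], ["sensitive", "resistant"])

    def test_balanced_accuracy_identity_holds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(4, 50))
            truth = rng.choice(["sensitive", "resistant"], size=n)
            pred = rng.choice(["sensitive", "resistant"], size=n)
            if len(set(truth)) < 2:
                continue
            r = confusion_metrics(truth, pred)
            assert r.balanced_accuracy == (r.sensitivity + r.specificity) / 2


class TestAuroc:
    def test_perfect_ranking(self):
        assert auroc(["sensitive", "sensitive", "resistant"], [3, 2, 1]) == 1.0

    def test_all_ties_half(self):
        assert auroc(["sensitive", "resistant"], [1.0, 1.0]) == 0.5

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pair_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        truth = rng.permutation(["sensitive"] * (n // 3 + 1)
                                + ["resistant"] * (n - n // 3 - 1))
        scores = rng.integers(0, 6, size=n).astype(float)
        assert auroc(truth, scores) == pytest.approx(
            brute_force_auroc(truth, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc(["sensitive", "sensitive"], [1.0, 2.0])


class TestDrugInclusionFilter:
    def test_boundary_tuples(self):
        counts = {"in": (20, 20, 10, 10), "out": (19, 40, 10, 10)}
        assert drug_inclusion_filter(counts) == ["in"]

    @pytest.mark.parametrize("bad", [(20, 20, 10, 9), (20, 19, 10, 10),
                                     (0, 0, 0, 0), (19, 20, 10, 10)])
    def test_each_threshold_binds(self, bad):
        assert drug_inclusion_filter({"d": bad}) == []

    def test_empty_input(self):
        assert drug_inclusion_filter({}) == []

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            drug_inclusion_filter({"d": (-1, 5, 5, 5)})


class TestSdssGroupTest:
    def test_wrong_direction_large_p(self):
        # predicted-sensitive values BELOW predicted-resistant: one-sided p >= 0.5
        vals = list(range(10)) + list(range(20, 30))
        labels = ["sensitive"] * 10 + ["resistant"] * 10
        out = sdss_group_test({"d": (vals, labels)})
        assert out.loc["d", "p_value"] >= 0.5

    def test_right_direction_small_p(self):
        vals = list(range(20, 30)) + list(range(10))
        labels = ["sensitive"] * 10 + ["resistant"] * 10
        out = sdss_group_test({"d": (vals, labels)})
        assert out.loc["d", "p_value"] < 0.01

    def test_single_drug_adjusted_equals_raw(self):
        vals = [5, 6, 7, 1, 2, 3]
        labels = ["sensitive"] * 3 + ["resistant"] * 3
        out = sdss_group_test({"d": (vals, labels)})
        assert out.loc["d", "p_adjusted"] == pytest.approx(out.loc["d", "p_value"])

    def test_bh_adjustment_matches_stepup_oracle(self):
        rng = np.random.default_rng(5)
        per_drug = {}
        for i in range(6):
            shift = rng.uniform(0, 3)
            vals = np.concatenate([rng.normal(shift, 1, 8), rng.normal(0, 1, 8)])
            labels = ["sensitive"] * 8 + ["resistant"] * 8
            per_drug[f"d{i}"] = (vals, labels)
        out = sdss_group_test(per_drug)
        expected = bh_stepup(out["p_value"].to_numpy())
        np.testing.assert_allclose(out["p_adjusted"].to_numpy(), expected, rtol=1e-12)
        # monotone: adjusted preserves raw ordering, never below raw
        assert (out["p_adjusted"] >= out["p_value"] - 1e-15).all()
        raw_order = out["p_value"].sort_values().index
        assert (out.loc[raw_order, "p_adjusted"].diff().dropna() >= -1e-15).all()

    def test_untestable_drug_flagged_not_p1(self):
        per_drug = {
            "ok": ([3.0, 4.0, 1.0, 0.5], ["sensitive", "sensitive", "resistant", "resistant"]),
            "allres": ([1.0, 2.0], ["resistant", "resistant"]),
        }
        out = sdss_group_test(per_drug)
        assert not out.loc["allres", "tested"]
        assert np.isnan(out.loc["allres", "p_value"])

    def test_nothing_testable_rejected(self):
        with pytest.raises(ValueError):
            sdss_group_test({"d": ([1.0, 2.0], ["resistant", "resistant"])})


class TestRuleCompliance:
    def _model(self):
        return KTSPResults([TSPRule("A0", "B0", 0.9, 1.0),
                            TSPRule("A1", "B1", 0.8, 1.0)])

    def test_full_compliance_gives_plus_k_everywhere(self):
        model = self._model()
        df = pd.DataFrame(
            {"s1": [2, 1, 2, 1], "s2": [3, 0, 5, 2]},
            index=["A0", "B0", "A1", "B1"], dtype=float)
        profile = rule_compliance_profile(model, df, {"s1": "g1", "s2": "g2"})
        assert (profile.vote_sums == 2).all()
        assert profile.summary.loc["g1", "mean"] == profile.summary.loc["g2", "mean"]

    def test_unknown_tag_rejected(self):
        model = self._model()
        df = pd.DataFrame({"s1": [2, 1, 2, 1]}, index=["A0", "B0", "A1", "B1"],
                          dtype=float)
        with pytest.raises(ValueError, match="s1"):
            rule_compliance_profile(model, df, {})

    def test_missing_gene_named(self):
        model = self._model()
        df = pd.DataFrame({"s1": [2, 1, 2]}, index=["A0", "B0", "A1"], dtype=float)
        with pytest.raises(KeyError, match="B1"):
            rule_compliance_profile(model, df, {"s1": "g"})

    def test_null_groups_ci_covers_zero(self):
        """Two groups from one generator: the CI should usually cover 0."""
        model = self._model()
        covered = 0
        reps = 60
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(rng.normal(size=(4, 40)),
                              index=["A0", "B0", "A1", "B1"],
                              columns=[f"s{j}" for j in range(40)])
            groups = {f"s{j}": ("a" if j < 20 else "b") for j in range(40)}
            p = rule_compliance_profile(model, df, groups, n_boot=300, seed=seed)
            covered += p.ci_low <= 0.0 <= p.ci_high
        assert covered / reps >= 0.90


class TestGeneRecurrence:
    def test_disjoint_models_all_unique(self):
        m1 = KTSPResults([TSPRule("A", "B", 0.9, 1.0)])
        m2 = KTSPResults([TSPRule("C", "D", 0.9, 1.0)])
        table, frac = gene_recurrence({"d1": m1, "d2": m2})
        assert frac == 1.0
        assert set(table.index) == {"A", "B", "C", "D"}
        assert (table["n_classifiers"] == 1).all()

    def test_duplicated_model_counts_twice(self):
        m = KTSPResults([TSPRule("A", "B", 0.9, 1.0)])
        table, frac = gene_recurrence({"d1": m, "d2": m})
        assert (table["n_classifiers"] == 2).all()
        assert frac == 0.0

    def test_orientation_reported_per_drug(self):
        m1 = KTSPResults([TSPRule("A", "B", 0.9, 1.0)])
        m2 = KTSPResults([TSPRule("C", "A", 0.9, 1.0)])
        table, _ = gene_recurrence({"d1": m1, "d2": m2})
        assert table.loc["A", "n_classifiers"] == 2
        assert "d1:up_in_sensitive" in table.loc["A", "orientation"]
        assert "d2:down_in_sensitive" in table.loc["A", "orientation"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gene_recurrence({})
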