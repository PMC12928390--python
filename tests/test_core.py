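"""kTSP training, voting, and the rank-invariance robustness property."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ktsp.core import (
    KTSP,
    KTSPResults,
    TSPRule,
    check_rank_invariance,
    fit_ktsp,
    pair_score,
    rank_disjoint_pairs,
    select_k,
)
from ktsp.simulate import SyntheticConfig, generate_cohort

from conftest import separable_toy


def brute_force_delta(a, b, labels):
    """Exhaustive ordering count: the independent oracle for delta."""
    sens = np.asarray([l == "sensitive" if isinstance(l, str) else bool(l)
                       for l in labels])
    def frac(mask):
        wins = sum(1.0 if x > y else (0.5 if x == y else 0.0)
                   for x, y in zip(np.asarray(a)[mask], np.asarray(b)[mask]))
        return wins / mask.sum()
    return abs(frac(sens) - frac(~sens))


class TestPairScore:
    def test_perfect_separation_delta_one(self):
        a = [5, 6, 1, 2]
        b = [1, 2, 5, 6]
        labels = ["sensitive", "sensitive", "resistant", "resistant"]
        delta, _ = pair_score(a, b, labels)
        assert delta == 1.0

    def test_equal_fractions_delta_zero(self):
        a = [5, 1, 5, 1]
        b = [1, 5, 1, 5]
        labels = ["sensitive", "sensitive", "resistant", "resistant"]
        delta, _ = pair_score(a, b, labels)
        assert delta == 0.0

    def test_ties_count_half(self):
        a = [2.0, 2.0, 1.0, 3.0]
        b = [2.0, 2.0, 3.0, 1.0]
        labels = ["sensitive", "sensitive", "resistant", "resistant"]
        delta, _ = pair_score(a, b, labels)
        assert delta == pytest.approx(0.0)  # 0.5 vs (0+1)/2

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        a = rng.normal(size=n).round(1)  # rounding forces occasional ties
        b = rng.normal(size=n).round(1)
        labels = rng.permutation(["sensitive"] * (n // 2) + ["resistant"] * (n - n // 2))
        delta, _ = pair_score(a, b, labels)
        assert delta == pytest.approx(brute_force_delta(a, b, labels), abs=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            pair_score([1, 2], [2, 1], ["sensitive", "sensitive"])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_oracle_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        a = rng.integers(0, 5, size=n).astype(float)  # heavy ties
        b = rng.integers(0, 5, size=n).astype(float)
        n_s = int(rng.integers(1, n))
        labels = np.array(["sensitive"] * n_s + ["resistant"] * (n - n_s))
        delta, _ = pair_score(a, b, labels)
        assert delta == pytest.approx(brute_force_delta(a, b, labels), abs=1e-12)


class TestRankDisjointPairs:
    def test_greedy_disjointness(self):
        # G1>G2 separates perfectly; (G1, G3) nearly; G3/G4 weakly via noise
        df = pd.DataFrame(
            [
                [9.0, 9.0, 9.0, 1.0, 1.0, 1.0],   # G1
                [1.0, 1.0, 1.0, 9.0, 9.0, 9.0],   # G2
                [2.0, 2.0, 8.0, 8.0, 8.0, 2.0],   # G3
                [3.0, 3.0, 3.0, 7.0, 7.0, 3.0],   # G4
            ],
            index=["G1", "G2", "G3", "G4"],
            columns=list("abcdef"),
        )
        labels = ["sensitive"] * 3 + ["resistant"] * 3
        rules = rank_disjoint_pairs(df, labels, max_pairs=4)
        assert {rules[0].gene_a, rules[0].gene_b} == {"G1", "G2"}
        genes = [g for r in rules for g in (r.gene_a, r.gene_b)]
        assert len(genes) == len(set(genes))

    def test_two_genes_one_rule(self):
        df, labels = separable_toy()
        rules = rank_disjoint_pairs(df, labels, max_pairs=5)
        assert len(rules) == 1
        assert (rules[0].gene_a, rules[0].gene_b) == ("GA", "GB")

    def test_orientation_follows_sensitive_class(self):
        df, labels = separable_toy()
        flipped = ["resistant" if l == "sensitive" else "sensitive" for l in labels]
        rules = rank_disjoint_pairs(df, flipped, max_pairs=5)
        assert (rules[0].gene_a, rules[0].gene_b) == ("GB", "GA")

    def test_fewer_than_two_genes_rejected(self):
        df = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["G1"])
        with pytest.raises(ValueError):
            rank_disjoint_pairs(df, ["sensitive", "resistant"], 3)

    def test_embedded_pairs_recovered(self):
        """5 embedded pairs among 200 genes (θ=0.95, 60/60) land in the top 5."""
        hits = 0
        reps = 100
        for seed in range(reps):
            cohort = generate_cohort(
                SyntheticConfig(n_genes=200, n_sensitive=60, n_resistant=60,
                                n_truth_pairs=5, pair_fidelity=0.95, seed=seed)
            )
            rules = rank_disjoint_pairs(cohort.expression, cohort.labels, max_pairs=5)
            fitted = {(r.gene_a, r.gene_b) for r in rules}
            hits += fitted == set(cohort.truth_pairs)
        assert hits / reps >= 0.95


class TestSelectK:
    def test_single_candidate(self):
        df, labels = separable_toy()
        rules = rank_disjoint_pairs(df, labels, 1)
        assert select_k(df, labels, rules) == 1

    def test_k_stays_in_bounds(self, small_cohort):
        rules = rank_disjoint_pairs(small_cohort.expression, small_cohort.labels, 15)
        k = select_k(small_cohort.expression, small_cohort.labels, rules)
        assert 1 <= k <= 15

    def test_noise_rules_do_not_inflate_k(self):
        """One perfect rule plus coin-flip rules: k = 1 nearly always."""
        wins = 0
        reps = 100
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            n = 40
            labels = np.array(["sensitive"] * 20 + ["resistant"] * 20)
            sens = labels == "sensitive"
            X = rng.normal(size=(12, n))
            X[0, sens] = 5.0   # perfect pair (gene 0, gene 1)
            X[0, ~sens] = -5.0
            X[1] = 0.0
            df = pd.DataFrame(X, index=[f"G{i}" for i in range(12)],
                              columns=[f"s{j}" for j in range(n)])
            perfect = TSPRule("G0", "G1", 1.0, 1.0)
            noise = [TSPRule(f"G{2*i}", f"G{2*i+1}", 0.1, 0.1) for i in range(1, 6)]
            wins += select_k(df, labels, [perfect] + noise) == 1
        assert wins / reps >= 0.90

    def test_empty_candidates_rejected(self):
        df, labels = separable_toy()
        with pytest.raises(ValueError):
            select_k(df, labels, [])


class TestFitAndPredict:
    def test_separable_toy_gives_k1_model(self):
        df, labels = separable_toy()
        res = fit_ktsp(df, labels)
        assert res.k == 1
        assert (res.rules[0].gene_a, res.rules[0].gene_b) == ("GA", "GB")
        assert list(res.predict(df)) == labels

    def test_single_class_rejected(self):
        df, _ = separable_toy()
        with pytest.raises(ValueError):
            fit_ktsp(df, ["sensitive"] * 4)

    def test_training_is_deterministic(self, small_cohort):
        r1 = fit_ktsp(small_cohort.expression, small_cohort.labels)
        r2 = fit_ktsp(small_cohort.expression, small_cohort.labels)
        assert r1.k == r2.k
        assert [(a.gene_a, a.gene_b) for a in r1.rules] == \
               [(a.gene_a, a.gene_b) for a in r2.rules]

    def test_vote_sum_extremes_and_counting(self):
        rules = [TSPRule(f"A{i}", f"B{i}", 0.9, 1.0) for i in range(3)]
        model = KTSPResults(rules)
        all_yes = {f"A{i}": 2.0 for i in range(3)} | {f"B{i}": 1.0 for i in range(3)}
        all_no = {f"A{i}": 1.0 for i in range(3)} | {f"B{i}": 2.0 for i in range(3)}
        two_of_three = dict(all_yes, A2=0.0)
        assert model.vote_sum(all_yes) == 3
        assert model.vote_sum(all_no) == -3
        assert model.vote_sum(two_of_three) == 1
        assert model.decision_score(all_yes) == 1.0

    def test_expression_tie_votes_against(self):
        model = KTSPResults([TSPRule("A", "B", 0.9, 1.0)])
        assert model.vote_sum({"A": 1.0, "B": 1.0}) == -1

    def test_missing_gene_named_in_error(self):
        model = KTSPResults([TSPRule("A", "B", 0.9, 1.0)])
        with pytest.raises(KeyError, match="B"):
            model.vote_sum({"A": 1.0})

    def test_majority_and_tie_policy(self):
        rules2 = [TSPRule("A0", "B0", 0.9, 1.0), TSPRule("A1", "B1", 0.8, 1.0)]
        model = KTSPResults(rules2)  # default tie -> resistant
        tied = {"A0": 2.0, "B0": 1.0, "A1": 1.0, "B1": 2.0}
        assert model.predict_one(tied) == "resistant"
        model_s = KTSPResults(rules2, tie_policy="sensitive")
        assert model_s.predict_one(tied) == "sensitive"

    def test_label_flip_negates_votes(self, small_cohort):
        expr, labels = small_cohort.expression, small_cohort.labels
        flipped = labels.map({"sensitive": "resistant", "resistant": "sensitive"})
        r1 = rank_disjoint_pairs(expr, labels, 10)
        r2 = rank_disjoint_pairs(expr, flipped, 10)
        pairs1 = {(r.gene_a, r.gene_b) for r in r1}
        pairs2 = {(r.gene_b, r.gene_a) for r in r2}
        assert pairs1 == pairs2
        m1 = KTSPResults(r1)
        m2 = KTSPResults([TSPRule(r.gene_a, r.gene_b, r.delta, r.gamma) for r in r2])
        vs1 = m1.vote_sums(expr.values)
        vs2 = m2.vote_sums(expr.values)
        # every comparison flips except exact expression ties (absent here)
        assert (vs1 == -vs2).all()

    def test_rules_are_gene_disjoint_requirement(self):
        with pytest.raises(ValueError):
            KTSPResults([TSPRule("A", "B", 0.9, 1.0), TSPRule("B", "C", 0.8, 1.0)])


class TestRankInvariance:
    def test_affine_transform(self, small_cohort):
        model = fit_ktsp(small_cohort.expression, small_cohort.labels)
        assert check_rank_invariance(model, small_cohort.expression,
                                     lambda x: 2 * x + 7)

    def test_cubic_transform(self, small_cohort):
        model = fit_ktsp(small_cohort.expression, small_cohort.labels)
        assert check_rank_invariance(model, small_cohort.expression,
                                     lambda x: x ** 3)

    def test_per_sample_mixture_of_monotone_maps(self, small_cohort):
        model = fit_ktsp(small_cohort.expression, small_cohort.labels)
        n = small_cohort.expression.shape[1]
        rng = np.random.default_rng(7)
        maps = [
            (lambda x: np.exp(x / 4)) if rng.uniform() < 0.5 else (lambda x: x ** 3)
            for _ in range(n)
        ]
        assert check_rank_invariance(model, small_cohort.expression, maps)

    def test_decreasing_transform_rejected(self, small_cohort):
        model = fit_ktsp(small_cohort.expression, small_cohort.labels)
        with pytest.raises(ValueError, match="increasing"):
            check_rank_invariance(model, small_cohort.expression, lambda x: -x)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, small_cohort):
        model = fit_ktsp(small_cohort.expression, small_cohort.labels)
        path = tmp_path / "rules.csv"
        model.save(path, drug="venetoclax")
        loaded = KTSPResults.load(path)
        assert loaded.k == model.k
        assert [(r.gene_a, r.gene_b) for r in loaded.rules] == \
               [(r.gene_a, r.gene_b) for r in model.rules]
        assert loaded.tie_policy == model.tie_policy
        before = model.predict(small_cohort.expression.values)
        after = loaded.predict(small_cohort.expression.values)
        assert (before == after).all()

    def test_summary_lists_all_rules(self, small_cohort):
        model = fit_ktsp(small_cohort.expression, small_cohort.labels)
        text = model.summary()
        for rule in model.rules:
            assert rule.gene_a in text and rule.gene_b in text
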