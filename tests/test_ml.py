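"""Attribute weighting, supervised classification, decision-rule extraction."""

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeClassifier

from extremocodon.ml import (
    WEIGHTING_ALGORITHMS,
    FeatureTable,
    SplitSpec,
    attribute_weights,
    extract_rules,
    render_rule,
    root_feature,
    support_counts,
    train_eval,
)
from extremocodon.significance import filter_significant


def make_table(columns: dict[str, list[float]], labels: list[str],
               groups=None) -> FeatureTable:
    return FeatureTable(
        X=pd.DataFrame(columns), y=pd.Series(labels, name="label"),
        groups=pd.Series(groups) if groups is not None else None,
    )


@pytest.fixture
def separable_table():
    """AGG perfectly separates; CCC is constant; AAA is pure noise."""
    rng = np.random.default_rng(5)
    n = 40
    y = ["hot"] * n + ["cold"] * n
    agg = np.r_[rng.uniform(5, 6, n), rng.uniform(1, 2, n)]
    return make_table(
        {"AGG": agg, "CCC": np.ones(2 * n), "AAA": rng.uniform(0, 10, 2 * n)}, y
    )


class TestAttributeWeights:
    def test_perfect_separator_gets_weight_one_everywhere(self, separable_table):
        wm = attribute_weights(separable_table)
        assert set(wm.algorithms) == set(WEIGHTING_ALGORITHMS)
        assert np.allclose(wm.weights.loc["AGG"], 1.0)

    def test_constant_feature_gets_weight_zero_everywhere(self, separable_table):
        wm = attribute_weights(separable_table)
        assert np.allclose(wm.weights.loc["CCC"], 0.0)

    def test_weights_bounded_in_unit_interval(self, separable_table):
        wm = attribute_weights(separable_table)
        assert ((wm.weights >= 0) & (wm.weights <= 1)).all().all()

    def test_shifted_codon_outweighs_null_codons(self, biased_paired):
        paired, _ = biased_paired
        table = FeatureTable.from_paired(paired, filter_significant(paired, alpha=1.0))
        wm = attribute_weights(table)
        null_codons = [c for c in ("AAA", "TTT", "GGG", "CCA") if c in wm.weights.index]
        for algo in wm.algorithms:
            for null in null_codons:
                assert wm.weights.loc["AGG", algo] > wm.weights.loc[null, algo], algo

    def test_scale_free_algorithms_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(11)
        y = ["a"] * 30 + ["b"] * 30
        base = {"AGG": rng.normal(2, 1, 60) + np.r_[np.ones(30), np.zeros(30)],
                "CAA": rng.uniform(0, 5, 60)}
        t1 = make_table(base, y)
        t2 = make_table({"AGG": 10 * base["AGG"] + 3, "CAA": base["CAA"]}, y)
        for algo in ("correlation", "relief"):
            w1 = attribute_weights(t1, algorithms=[algo]).weights
            w2 = attribute_weights(t2, algorithms=[algo]).weights
            assert np.allclose(w1, w2, atol=1e-9), algo

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            make_table({"AGG": [1, 2, 3]}, ["x", "x", "x"])

    def test_plugin_weighter(self, separable_table):
        def span(x, y):
            return float(x.max() - x.min())

        wm = attribute_weights(separable_table, algorithms=["span"],
                               extra_weighters={"span": span})
        assert list(wm.algorithms) == ["span"]


class TestSupportCounts:
    def test_threshold_counting(self):
        from extremocodon.ml import WeightMatrix

        weights = pd.DataFrame({"a1": [0.9, 0.2], "a2": [0.6, 0.0],
                                "a3": [0.4, 1.0]}, index=["AGG", "CAA"])
        counts = support_counts(WeightMatrix(weights))
        assert counts.counts["AGG"] == 2
        assert counts.counts["CAA"] == 1

    def test_zero_threshold_counts_all(self):
        from extremocodon.ml import WeightMatrix

        weights = pd.DataFrame({"a1": [0.0], "a2": [0.3]}, index=["AGG"])
        assert support_counts(WeightMatrix(weights), threshold=0).counts["AGG"] == 2


class TestTrainEval:
    def test_strong_bias_knn_is_highly_accurate(self, biased_paired):
        paired, _ = biased_paired
        table = FeatureTable.from_paired(paired, filter_significant(paired))
        report = train_eval(table, "knn", SplitSpec(seed=1), k=10)
        assert report.accuracy >= 85.0
        assert report.n_train + report.n_test == 2 * paired.n_pairs

    def test_determinism(self, biased_paired):
        paired, _ = biased_paired
        table = FeatureTable.from_paired(paired, filter_significant(paired))
        r1 = train_eval(table, "tree", SplitSpec(seed=3), criterion="infogain")
        r2 = train_eval(table, "tree", SplitSpec(seed=3), criterion="infogain")
        assert r1 == r2

    def test_group_split_keeps_pairs_together(self, biased_paired):
        paired, _ = biased_paired
        table = FeatureTable.from_paired(paired, filter_significant(paired))
        from sklearn.model_selection import GroupShuffleSplit

        splitter = GroupShuffleSplit(n_splits=1, train_size=0.7, random_state=5)
        train_idx, test_idx = next(splitter.split(table.X, table.y, table.groups))
        train_groups = set(table.groups.iloc[train_idx])
        test_groups = set(table.groups.iloc[test_idx])
        assert not train_groups & test_groups
        # one row per class per pair makes the split exactly balanced
        assert table.y.iloc[train_idx].value_counts().nunique() == 1

    @pytest.mark.parametrize("model", ["nb", "logreg", "forest"])
    def test_other_models_run_and_report_percent(self, model, biased_paired):
        paired, _ = biased_paired
        table = FeatureTable.from_paired(paired, filter_significant(paired))
        report = train_eval(table, model, SplitSpec(seed=2))
        assert 0.0 <= report.accuracy <= 100.0

    def test_unknown_model_rejected(self, biased_paired):
        paired, _ = biased_paired
        table = FeatureTable.from_paired(paired, filter_significant(paired))
        with pytest.raises(ValueError, match="unknown model"):
            train_eval(table, "chaid", SplitSpec(seed=0))


class TestExtractRules:
    def fit_tree(self, X, y, **kw):
        clf = DecisionTreeClassifier(random_state=0, **kw)
        clf.fit(X, y)
        return clf

    def test_depth_one_tree_gives_two_rules(self):
        X = np.array([[1.0], [2.0], [8.0], [9.0]])
        y = np.array(["A", "A", "B", "B"])
        clf = self.fit_tree(X, y, max_depth=1)
        rules = extract_rules(clf, ["CAA"])
        assert len(rules) == 2
        thr = rules[0].conditions[0][2]
        assert render_rule(rules[0]) == f"If % CAA (≤{thr:.3f}] → A"
        assert render_rule(rules[1]) == f"If % CAA (>{thr:.3f}] → B"

    def test_single_leaf_tree_yields_no_rules(self, caplog):
        X = np.array([[1.0], [1.0]])
        y = np.array(["A", "A"])
        clf = self.fit_tree(X, y)
        assert extract_rules(clf, ["CAA"]) == []

    def test_two_condition_rendering_grammar(self):
        # grammar: If % GAC (>8.861] and % AGG (≤1.441] → Non-halophile
        from extremocodon.ml import DecisionRule

        rule = DecisionRule(
            conditions=(("GAC", "≤", 8.861), ("AGG", ">", 1.441)),
            label="Non-halophile",
        )
        assert render_rule(rule) == "If % GAC (≤8.861] and % AGG (>1.441] → Non-halophile"

    def test_root_split_names_the_most_shifted_codon(self, biased_paired):
        paired, _ = biased_paired
        table = FeatureTable.from_paired(paired, filter_significant(paired))
        clf = self.fit_tree(table.X.to_numpy(), table.y.to_numpy(),
                            criterion="entropy", max_depth=3)
        rules = extract_rules(clf, list(table.X.columns))
        assert root_feature(rules) in {"AGG", "CAA", "CAG"}  # the shifted family
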