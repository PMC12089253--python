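"""Fixed risk rule, Gini impurity, CART learner vs an exhaustive oracle,
and bootstrap internal validation."""

import numpy as np
import pandas as pd
import pytest

from observezone.grace import GraceAssessment, grace_category
from observezone.panel import BiomarkerPanelResult, MarkerStatus
from observezone.pipeline import annotate_cohort
from observezone.stratify import (
    CartParams,
    RiskStratum,
    assign_stratum,
    bootstrap_validate,
    fit_cart,
    gini_impurity,
)
from observezone.synthetic import generate_cohort, strong_grace_config


def _grace(score):
    return GraceAssessment(score=score, category=grace_category(score))


def _panel(count):
    status = {m: MarkerStatus.MISSING for m in
              ("crp", "ntprobnp", "ddimer", "egfr", "copeptin", "hemoglobin")}
    for m in list(status)[:count]:
        status[m] = MarkerStatus.ABNORMAL
    return BiomarkerPanelResult(status=status, abnormal_count=count, measured_count=count)


@pytest.mark.parametrize(
    "score, count, stratum",
    [
        (95, 0, RiskStratum.LOW_GRACE_0_ABNORMAL),
        (95, 1, RiskStratum.LOW_GRACE_LE1_ABNORMAL),
        (95, 2, RiskStratum.LOW_GRACE_GT1_ABNORMAL),
        (95, 5, RiskStratum.LOW_GRACE_GT1_ABNORMAL),
        (151, 0, RiskStratum.NOT_LOW_GRACE),  # GRACE gate dominates
        (109, 0, RiskStratum.NOT_LOW_GRACE),
        (108, 0, RiskStratum.LOW_GRACE_0_ABNORMAL),
    ],
)
def test_fixed_rule(score, count, stratum):
    assert assign_stratum(_grace(score), _panel(count)) is stratum


@pytest.mark.parametrize(
    "deaths, n, expected",
    [(0, 100, 0.0), (100, 100, 0.0), (50, 100, 0.5), (49, 961, 0.09678)],
)
def test_gini_values(deaths, n, expected):
    assert gini_impurity(deaths, n) == pytest.approx(expected, abs=5e-6)


def test_gini_undefined_for_empty_node():
    with pytest.raises(ValueError):
        gini_impurity(0, 0)


# ---------------------------------------------------------------------------
# exhaustive-search oracle (independent of the implementation)
# ---------------------------------------------------------------------------


def _oracle_tree(rows, features, max_depth, min_leaf):
    def imp(rs):
        d = sum(r["death"] for r in rs)
        p = d / len(rs)
        return 2 * p * (1 - p)

    def build(rs, depth):
        node = {"n": len(rs), "deaths": sum(r["death"] for r in rs)}
        if depth >= max_depth or len(rs) < 2 * min_leaf or node["deaths"] in (0, len(rs)):
            return node
        best = None
        for f in features:
            vals = sorted({r[f] for r in rs})
            for a, b in zip(vals, vals[1:]):
                thr = (a + b) / 2
                left = [r for r in rs if r[f] <= thr]
                right = [r for r in rs if r[f] > thr]
                if len(left) < min_leaf or len(right) < min_leaf:
                    continue
                gain = imp(rs) - (len(left) * imp(left) + len(right) * imp(right)) / len(rs)
                if best is None or gain > best[0] + 1e-12:
                    best = (gain, f, thr, left, right)
        if best is None or best[0] <= 1e-12:
            return node
        node.update(feature=best[1], threshold=best[2],
                    left=build(best[3], depth + 1), right=build(best[4], depth + 1))
        return node

    return build(rows, 0)


def _assert_same_tree(node, oracle):
    assert node.n == oracle["n"] and node.deaths == oracle["deaths"]
    if "feature" in oracle:
        assert node.feature == oracle["feature"]
        assert node.threshold == pytest.approx(oracle["threshold"])
        _assert_same_tree(node.left, oracle["left"])
        _assert_same_tree(node.right, oracle["right"])
    else:
        assert node.is_leaf


def _random_instances(n_instances, seed):
    rng = np.random.default_rng(seed)
    for _ in range(n_instances):
        n = int(rng.integers(8, 51))
        df = pd.DataFrame(
            {
                "grace_score": rng.integers(0, 6, n).astype(float),
                "abnormal_count": rng.integers(0, 4, n).astype(float),
                "death": rng.random(n) < 0.35,
            }
        )
        yield df


@pytest.mark.parametrize("max_depth, min_leaf", [(2, 2), (2, 5), (3, 2)])
def test_cart_matches_exhaustive_oracle_on_small_instances(max_depth, min_leaf):
    for df in _random_instances(25, seed=202):
        tree = fit_cart(df, params=CartParams(max_depth=max_depth, min_leaf=min_leaf))
        oracle = _oracle_tree(df.to_dict("records"),
                              ["grace_score", "abnormal_count"], max_depth, min_leaf)
        _assert_same_tree(tree.root, oracle)


def test_two_feature_toy_with_known_best_split():
    # 8 records: deaths perfectly separated by x <= 0.5; y is noise
    df = pd.DataFrame(
        {"x": [0, 0, 0, 0, 1, 1, 1, 1], "y": [0, 1, 0, 1, 0, 1, 0, 1],
         "death": [False] * 4 + [True] * 4}
    )
    tree = fit_cart(df, params=CartParams(max_depth=2, min_leaf=2))
    assert tree.root.feature == "x" and tree.root.threshold == 0.5
    assert tree.root.left.event_rate == 0.0 and tree.root.right.event_rate == 1.0


def test_all_survivors_single_leaf():
    df = pd.DataFrame({"x": range(100), "death": [False] * 100})
    tree = fit_cart(df)
    assert tree.root.is_leaf and tree.root.event_rate == 0.0


def test_identical_features_single_leaf():
    df = pd.DataFrame({"x": [1.0] * 50, "death": [True] * 10 + [False] * 40})
    assert fit_cart(df).root.is_leaf


def test_integer_feature_splits_at_half_integers():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"abnormal_count": rng.integers(0, 4, 200)})
    df["death"] = df["abnormal_count"] > 1  # the '<= 1' rule exactly
    tree = fit_cart(df, params=CartParams(max_depth=1, min_leaf=5))
    assert tree.root.threshold == 1.5


def test_impurity_never_increases_root_to_leaf():
    cohort = generate_cohort(strong_grace_config(n=1000, seed=3))
    table = annotate_cohort(cohort)[["grace_score", "abnormal_count", "death"]]
    tree = fit_cart(table, params=CartParams(max_depth=3, min_leaf=10))

    def walk(node):
        if node.is_leaf:
            return
        weighted = (node.left.n * node.left.impurity
                    + node.right.n * node.right.impurity) / node.n
        assert weighted <= node.impurity + 1e-12
        walk(node.left)
        walk(node.right)

    walk(tree.root)


def test_fixed_rule_agrees_with_learned_tree_leaves():
    # when the fitted splits are exactly (grace < 109, count <= 1), leaf
    # membership must coincide with assign_stratum's coarse low/not-low and
    # <=1/>1 partition
    cohort = generate_cohort(strong_grace_config(n=2000, seed=11))
    ann = annotate_cohort(cohort)
    table = ann[["grace_score", "abnormal_count", "death"]]
    tree = fit_cart(table)
    assert tree.root.feature == "grace_score" and 108 <= tree.root.threshold <= 109
    for _, row in table.iloc[:200].iterrows():
        leaf_low = row["grace_score"] <= tree.root.threshold
        stratum = ann.loc[row.name, "stratum"]
        assert leaf_low == (stratum != RiskStratum.NOT_LOW_GRACE.value)


def test_bootstrap_on_constant_cohort_reproduces_tree():
    # every resample of identical records equals the original by construction
    df = pd.DataFrame({"x": [1.0] * 30, "death": [True] * 6 + [False] * 24})
    val = bootstrap_validate(df, CartParams(min_leaf=2), B=1, seed=0)
    assert val.n_unfit == 0
    assert val.reference_tree.root.is_leaf
    (path, interval), = val.leaf_rate_intervals.items()
    assert path == "root" and interval[0] == interval[1] == pytest.approx(0.2)


def test_bootstrap_requires_positive_B():
    df = pd.DataFrame({"x": [1.0, 2.0], "death": [True, False]})
    with pytest.raises(ValueError):
        bootstrap_validate(df, B=0)


def test_bootstrap_counts_degenerate_resamples():
    # a single death: many resamples miss it entirely and are unfit
    df = pd.DataFrame({"x": np.arange(40.0), "death": [True] + [False] * 39})
    val = bootstrap_validate(df, CartParams(min_leaf=2), B=50, seed=4)
    assert 0 < val.n_unfit < 50
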