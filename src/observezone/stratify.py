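"""Risk stratification: the fixed GRACE-then-biomarker rule and a CART learner.

The headline rule is a fixed two-level tree: patients with a GRACE 1.0 score
< 109 are split by the biomarker abnormal count (0, exactly 1, > 1); everyone
else is not-low-GRACE. A small CART (classification and regression tree)
learner with bootstrap internal validation is provided to rediscover that
tree from data; the fixed rule, not a refit, drives the reported metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .grace import GraceAssessment, GraceCategory
from .panel import BiomarkerPanelResult

__all__ = [
    "RiskStratum",
    "assign_stratum",
    "gini_impurity",
    "entropy_impurity",
    "CartParams",
    "CartNode",
    "CartTree",
    "fit_cart",
    "BootstrapValidation",
    "bootstrap_validate",
]


class RiskStratum(str, Enum):
    LOW_GRACE_0_ABNORMAL = "LOW_GRACE_0_ABNORMAL"
    LOW_GRACE_LE1_ABNORMAL = "LOW_GRACE_LE1_ABNORMAL"  # exactly one abnormal marker
    LOW_GRACE_GT1_ABNORMAL = "LOW_GRACE_GT1_ABNORMAL"
    NOT_LOW_GRACE = "NOT_LOW_GRACE"


def assign_stratum(grace: GraceAssessment, panel: BiomarkerPanelResult) -> RiskStratum:
    """Fixed rule: GRACE gate first, then the abnormal-marker count."""
    if grace.category is not GraceCategory.LOW:
        return RiskStratum.NOT_LOW_GRACE
    if panel.abnormal_count == 0:
        return RiskStratum.LOW_GRACE_0_ABNORMAL
    if panel.abnormal_count == 1:
        return RiskStratum.LOW_GRACE_LE1_ABNORMAL
    return RiskStratum.LOW_GRACE_GT1_ABNORMAL


def gini_impurity(deaths: int, n: int) -> float:
    """Binary Gini impurity 2*p*(1-p) with p = deaths/n; in [0, 0.5]."""
    if n <= 0:
        raise ValueError("gini_impurity undefined for n = 0")
    if not 0 <= deaths <= n:
        raise ValueError("deaths must lie in [0, n]")
    p = deaths / n
    return 2.0 * p * (1.0 - p)


def entropy_impurity(deaths: int, n: int) -> float:
    """Shannon entropy (nats) of the death/survive split; alternative criterion."""
    if n <= 0:
        raise ValueError("entropy_impurity undefined for n = 0")
    p = deaths / n
    if p in (0.0, 1.0):
        return 0.0
    return float(-(p * np.log(p) + (1 - p) * np.log(1 - p)))


_CRITERIA = {"gini": gini_impurity, "entropy": entropy_impurity}


@dataclass(frozen=True)
class CartParams:
    """Learner controls; defaults mirror the two-level published tree."""

    max_depth: int = 2
    min_leaf: int = 20
    criterion: str = "gini"

    def __post_init__(self):
        if self.max_depth < 0 or self.min_leaf < 1:
            raise ValueError("max_depth must be >= 0 and min_leaf >= 1")
        if self.criterion not in _CRITERIA:
            raise ValueError(f"criterion must be one of {sorted(_CRITERIA)}")


@dataclass
class CartNode:
    n: int
    deaths: int
    impurity: float
    feature: str | None = None     # None for leaves
    threshold: float | None = None  # left branch: value <= threshold
    left: "CartNode | None" = None
    right: "CartNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def event_rate(self) -> float:
        return self.deaths / self.n

    def to_dict(self) -> dict:
        d = {"n": self.n, "deaths": self.deaths, "impurity": self.impurity,
             "event_rate": self.event_rate}
        if not self.is_leaf:
            d.update(feature=self.feature, threshold=self.threshold,
                     left=self.left.to_dict(), right=self.right.to_dict())
        return d


@dataclass
class CartTree:
    root: CartNode
    features: tuple[str, ...]
    params: CartParams

    def predict_leaf(self, row) -> CartNode:
        node = self.root
        while not node.is_leaf:
            node = node.left if row[node.feature] <= node.threshold else node.right
        return node

    def leaves(self) -> list[tuple[str, CartNode]]:
        """(path, leaf) pairs; path encodes the splits taken, 'root' if trivial."""
        out: list[tuple[str, CartNode]] = []

        def walk(node: CartNode, path: str):
            if node.is_leaf:
                out.append((path or "root", node))
            else:
                walk(node.left, f"{path}{'&' if path else ''}{node.feature}<={node.threshold:g}")
                walk(node.right, f"{path}{'&' if path else ''}{node.feature}>{node.threshold:g}")

        walk(self.root, "")
        return out

    def to_dict(self) -> dict:
        return {"features": list(self.features),
                "params": {"max_depth": self.params.max_depth,
                           "min_leaf": self.params.min_leaf,
                           "criterion": self.params.criterion},
                "root": self.root.to_dict()}

    def format_text(self) -> str:
        lines: list[str] = []

        def walk(node: CartNode, indent: int, label: str):
            pad = "  " * indent
            stats = f"n={node.n} deaths={node.deaths} rate={node.event_rate:.4f}"
            if node.is_leaf:
                lines.append(f"{pad}{label}leaf: {stats}")
            else:
                lines.append(f"{pad}{label}split {node.feature} <= {node.threshold:g} ({stats})")
                walk(node.left, indent + 1, "L: ")
                walk(node.right, indent + 1, "R: ")

        walk(self.root, 0, "")
        return "\n".join(lines)


def _best_split(X: np.ndarray, y: np.ndarray, features: Sequence[str],
                impurity, min_leaf: int):
    """Greedy best (feature, threshold) by weighted-impurity decrease.

    Candidates are midpoints of consecutive unique observed values. Ties keep
    the first candidate in (feature order, ascending threshold) order.
    """
    n = len(y)
    parent = impurity(int(y.sum()), n)
    best = None
    best_gain = 0.0
    for j, feat in enumerate(features):
        x = X[:, j]
        u = np.unique(x)
        if len(u) < 2:
            continue
        thresholds = (u[:-1] + u[1:]) / 2.0
        for thr in thresholds:
            mask = x <= thr
            nl = int(mask.sum())
            nr = n - nl
            if nl < min_leaf or nr < min_leaf:
                continue
            dl = int(y[mask].sum())
            dr = int(y.sum()) - dl
            child = (nl * impurity(dl, nl) + nr * impurity(dr, nr)) / n
            gain = parent - child
            if gain > best_gain + 1e-12:
                best_gain = gain
                best = (feat, j, float(thr))
    return best, best_gain


def fit_cart(
    table: pd.DataFrame,
    features: Sequence[str] | None = None,
    params: CartParams = CartParams(),
) -> CartTree:
    """Greedy binary CART over the given feature columns.

    ``table`` needs a boolean/0-1 ``death`` column; ``features`` defaults to
    every other column in table order (that order breaks ties). Recursion
    stops at ``max_depth``, when a child would fall under ``min_leaf``, or at
    zero impurity gain; degenerate inputs yield a single-leaf tree.
    """
    if "death" not in table.columns:
        raise ValueError("table must contain a 'death' column")
    if features is None:
        features = tuple(c for c in table.columns if c != "death")
    features = tuple(features)
    if not features:
        raise ValueError("at least one feature column is required")
    X = table.loc[:, list(features)].to_numpy(dtype=float)
    y = table["death"].to_numpy(dtype=bool)
    impurity = _CRITERIA[params.criterion]

    def build(idx: np.ndarray, depth: int) -> CartNode:
        n = len(idx)
        deaths = int(y[idx].sum())
        node = CartNode(n=n, deaths=deaths, impurity=impurity(deaths, n))
        if depth >= params.max_depth or n < 2 * params.min_leaf or node.impurity == 0.0:
            return node
        best, _gain = _best_split(X[idx], y[idx], features, impurity, params.min_leaf)
        if best is None:
            return node
        feat, j, thr = best
        mask = X[idx, j] <= thr
        node.feature = feat
        node.threshold = thr
        node.left = build(idx[mask], depth + 1)
        node.right = build(idx[~mask], depth + 1)
        return node

    root = build(np.arange(len(y)), 0)
    return CartTree(root=root, features=features, params=params)


@dataclass
class BootstrapValidation:
    """Internal validation summary of the fitted tree."""

    B: int
    n_unfit: int                     # degenerate resamples (no deaths)
    root_match_fraction: float       # among fitted replicates
    root_features: dict = field(default_factory=dict)
    leaf_rate_intervals: dict = field(default_factory=dict)  # ref leaf path -> (lo, hi)
    reference_tree: CartTree | None = None


def bootstrap_validate(
    table: pd.DataFrame,
    params: CartParams = CartParams(),
    B: int = 1000,
    seed: int = 0,
    *,
    features: Sequence[str] | None = None,
    root_threshold_tol: float = 10.0,
) -> BootstrapValidation:
    """Refit the tree on B bootstrap resamples of size n.

    Reports the fraction of fitted replicates whose root split matches the
    reference tree (same feature, threshold within ``root_threshold_tol``)
    and 2.5-97.5 percentile intervals of the event rate each replicate's tree
    predicts for the rows of each reference leaf. Resamples without any death
    are recorded as unfit and excluded from both summaries.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    ref = fit_cart(table, features, params)
    rng = np.random.default_rng(seed)
    n = len(table)

    ref_leaf_of_row = [ref.predict_leaf(row) for _, row in table.iterrows()]
    paths = {id(leaf): path for path, leaf in ref.leaves()}
    groups: dict[str, list[int]] = {}
    for i, leaf in enumerate(ref_leaf_of_row):
        groups.setdefault(paths[id(leaf)], []).append(i)

    matches = 0
    unfit = 0
    root_features: dict[str, int] = {}
    rates: dict[str, list[float]] = {p: [] for p in groups}
    rows = list(table.iterrows())
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        sub = table.iloc[idx].reset_index(drop=True)
        if int(sub["death"].sum()) == 0:
            unfit += 1
            continue
        t = fit_cart(sub, features, params)
        if not t.root.is_leaf:
            root_features[t.root.feature] = root_features.get(t.root.feature, 0) + 1
        if (not ref.root.is_leaf and not t.root.is_leaf
                and t.root.feature == ref.root.feature
                and abs(t.root.threshold - ref.root.threshold) <= root_threshold_tol):
            matches += 1
        for path, members in groups.items():
            preds = [t.predict_leaf(rows[i][1]).event_rate for i in members]
            rates[path].append(float(np.mean(preds)))

    fitted = B - unfit
    intervals = {
        p: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5))) if v else (float("nan"),) * 2
        for p, v in rates.items()
    }
    return BootstrapValidation(
        B=B,
        n_unfit=unfit,
        root_match_fraction=matches / fitted if fitted else float("nan"),
        root_features=root_features,
        leaf_rate_intervals=intervals,
        reference_tree=ref,
    )
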