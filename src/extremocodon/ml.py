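"""Attribute weighting, supervised classification and decision-rule
extraction over significant-codon percentage features.

The feature table pools the CDS of both classes (one row per CDS, one
column per significant codon, values in %). Seven attribute-weighting
algorithms score each codon's discriminative value and are min-max
normalized to [0, 1] per algorithm; the support count of a codon is the
number of algorithms weighting it at or above 0.5.

Classifiers (k-NN with k = 10 by default, naive Bayes, logistic regression,
decision tree, random forest, and optional margin-classifier / feed-forward
network backends) are validated on a stratified 70/30 train/test split and
report held-out accuracy in %. Fitted trees are unrolled into one
root-to-leaf rule per leaf and rendered as, e.g.::

    If % GAC (>8.861] -> Halophile

with the comparator glyphs ``≤``/``>`` in the rendered text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupShuffleSplit, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .codon_model import CODON_INDEX
from .dataset_io import PairedDataset
from .significance import SignificantCodonSet

log = logging.getLogger(__name__)

N_BINS = 5  # equal-frequency bins for the discretizing weighters


@dataclass
class FeatureTable:
    """Pooled per-CDS percentage features for the significant codons.

    ``groups`` (optional) marks homologous-pair membership: both members of
    a pair carry the same group id. When present, train/test splitting is
    group-aware — a pair never straddles the split — because homologous
    twins share their amino-acid composition and would otherwise leak
    information across partitions.
    """

    X: pd.DataFrame          # rows: CDS; columns: codon strings
    y: pd.Series             # class label per row (2 distinct values)
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("X and y must have the same number of rows")
        if self.groups is not None and len(self.groups) != len(self.X):
            raise ValueError("groups must have one entry per row")
        if self.X.isna().any().any():
            raise ValueError("feature table contains missing values")
        labels = sorted(self.y.unique())
        if len(labels) != 2:
            raise ValueError(f"expected exactly 2 class labels, got {labels}")
        self.labels = labels

    @classmethod
    def from_paired(
        cls,
        paired: PairedDataset,
        sigset: SignificantCodonSet,
        labels: tuple[str, str] = ("extremophile", "non-extremophile"),
    ) -> "FeatureTable":
        """Pool both classes of a paired dataset over the significant codons."""
        if not sigset.codons:
            raise ValueError("empty significant set")
        cols = [CODON_INDEX[c] for c in sigset.codons]
        X = pd.DataFrame(
            np.vstack([paired.matrix_e[:, cols], paired.matrix_ne[:, cols]]),
            columns=list(sigset.codons),
        )
        y = pd.Series([labels[0]] * paired.n_pairs + [labels[1]] * paired.n_pairs,
                      name="label")
        groups = pd.Series(list(paired.pair_ids) * 2, name="pair_id")
        return cls(X=X, y=y, groups=groups)


# ---------------------------------------------------------------------------
# attribute weighting


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _discretize(x: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """Equal-frequency binning; collapsed bins (ties) are dropped."""
    binned = pd.qcut(x, q=n_bins, labels=False, duplicates="drop")
    return np.asarray(binned)


def _info_gain(x: np.ndarray, y: np.ndarray) -> float:
    bins = _discretize(x)
    h_y = _entropy(y)
    cond = 0.0
    for b in np.unique(bins):
        mask = bins == b
        cond += mask.mean() * _entropy(y[mask])
    return h_y - cond


def _gain_ratio(x: np.ndarray, y: np.ndarray) -> float:
    bins = _discretize(x)
    h_bins = _entropy(bins)
    if h_bins == 0.0:
        return 0.0
    return _info_gain(x, y) / h_bins


def _symmetric_uncertainty(x: np.ndarray, y: np.ndarray) -> float:
    bins = _discretize(x)
    h_bins = _entropy(bins)
    h_y = _entropy(y)
    if h_bins + h_y == 0.0:
        return 0.0
    return 2.0 * _info_gain(x, y) / (h_bins + h_y)


def _gini(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(1.0 - (p ** 2).sum())


def _gini_index(x: np.ndarray, y: np.ndarray) -> float:
    bins = _discretize(x)
    cond = 0.0
    for b in np.unique(bins):
        mask = bins == b
        cond += mask.mean() * _gini(y[mask])
    return _gini(y) - cond


def _chi_squared(x: np.ndarray, y: np.ndarray) -> float:
    bins = _discretize(x)
    table = pd.crosstab(bins, y).to_numpy(dtype=float)
    if table.shape[0] < 2:
        return 0.0
    total = table.sum()
    expected = table.sum(axis=1, keepdims=True) @ table.sum(axis=0, keepdims=True) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


def _correlation(x: np.ndarray, y: np.ndarray) -> float:
    y01 = (y == np.unique(y)[1]).astype(float)
    if x.std() == 0 or y01.std() == 0:
        return 0.0
    return float(abs(np.corrcoef(x, y01)[0, 1]))


def _relief(x_col: np.ndarray, X_scaled: np.ndarray, col: int, y: np.ndarray) -> float:
    """Classic Relief over every instance with a single nearest hit/miss.

    Distances use all features min-max scaled to [0, 1], so the weight is
    invariant under affine rescaling of any one column.
    """
    n = len(y)
    weight = 0.0
    for i in range(n):
        d = np.abs(X_scaled - X_scaled[i]).sum(axis=1)
        d[i] = np.inf
        same = y == y[i]
        hit_pool = np.where(same)[0]
        miss_pool = np.where(~same)[0]
        if hit_pool.size == 0 or miss_pool.size == 0:
            continue
        hit = hit_pool[np.argmin(d[hit_pool])]
        miss = miss_pool[np.argmin(d[miss_pool])]
        weight += (abs(X_scaled[i, col] - X_scaled[miss, col])
                   - abs(X_scaled[i, col] - X_scaled[hit, col]))
    return weight / n


WEIGHTING_ALGORITHMS = (
    "chi_squared",
    "info_gain",
    "gain_ratio",
    "gini_index",
    "correlation",
    "uncertainty",
    "relief",
)


@dataclass
class WeightMatrix:
    """codon x algorithm weights, min-max normalized to [0, 1] per algorithm."""

    weights: pd.DataFrame    # rows: codons; columns: algorithm names

    @property
    def algorithms(self) -> list[str]:
        return list(self.weights.columns)

    def to_dataframe(self) -> pd.DataFrame:
        out = self.weights.copy()
        out.insert(0, "codon", out.index)
        return out.reset_index(drop=True)


def attribute_weights(
    table: FeatureTable,
    algorithms: list[str] | None = None,
    extra_weighters: dict[str, callable] | None = None,
) -> WeightMatrix:
    """Weight every feature codon with each algorithm, min-max normalized.

    ``extra_weighters`` lets callers plug in additional scoring functions
    with signature ``f(x: ndarray, y: ndarray) -> float`` (higher = more
    discriminative); they are normalized like the built-ins.
    """
    if algorithms is None:
        algorithms = list(WEIGHTING_ALGORITHMS)
    for lbl in table.labels:
        if (table.y == lbl).sum() < 2:
            raise ValueError(f"class {lbl!r} has fewer than 2 rows")
    y = table.y.to_numpy()
    X = table.X.to_numpy(dtype=float)
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    X_scaled = (X - X.min(axis=0)) / span

    simple = {
        "chi_squared": _chi_squared,
        "info_gain": _info_gain,
        "gain_ratio": _gain_ratio,
        "gini_index": _gini_index,
        "correlation": _correlation,
        "uncertainty": _symmetric_uncertainty,
    }
    if extra_weighters:
        simple = {**simple, **extra_weighters}
    raw = {}
    for name in algorithms:
        if name == "relief":
            raw[name] = [_relief(X[:, j], X_scaled, j, y) for j in range(X.shape[1])]
        elif name in simple:
            raw[name] = [
                0.0 if X[:, j].std() == 0 else simple[name](X[:, j], y)
                for j in range(X.shape[1])
            ]
        else:
            raise ValueError(f"unknown weighting algorithm {name!r}")
    df = pd.DataFrame(raw, index=list(table.X.columns))
    lo, hi = df.min(axis=0), df.max(axis=0)
    rng = (hi - lo).replace(0, 1.0)
    norm = (df - lo) / rng
    # constant features carry no information; pin them to 0 even when a
    # negative raw score elsewhere (e.g. relief on noise) shifts the minimum
    constant = (X.max(axis=0) - X.min(axis=0)) == 0
    norm.loc[np.asarray(constant), :] = 0.0
    return WeightMatrix(weights=norm)


@dataclass
class SupportCounts:
    """Per codon: how many algorithms weighted it at/above the threshold."""

    counts: pd.Series
    threshold: float
    n_algorithms: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"codon": self.counts.index, "n_algorithms_ge_threshold": self.counts.values}
        )


def support_counts(wm: WeightMatrix, threshold: float = 0.5) -> SupportCounts:
    if wm.weights.empty:
        raise ValueError("empty weight matrix")
    counts = (wm.weights >= threshold).sum(axis=1)
    return SupportCounts(counts=counts, threshold=threshold,
                         n_algorithms=len(wm.algorithms))


# ---------------------------------------------------------------------------
# supervised classification

#: tree-criterion names accepted on the surface; the scikit-learn backend
#: exposes entropy and Gini impurity, onto which the four names map.
CRITERION_MAP = {
    "infogain": "entropy",
    "gainratio": "entropy",
    "gini": "gini",
    "accuracy": "gini",
}


@dataclass(frozen=True)
class SplitSpec:
    train_frac: float = 0.7
    seed: int = 0


@dataclass
class ClassifierReport:
    model: str
    hyperparameters: dict
    train_frac: float
    seed: int
    accuracy: float          # %, held-out rows only
    n_train: int
    n_test: int

    def to_dict(self) -> dict:
        return {
            "model": self.model, "hyperparameters": self.hyperparameters,
            "train_frac": self.train_frac, "seed": self.seed,
            "accuracy_pct": self.accuracy,
            "n_train": self.n_train, "n_test": self.n_test,
        }


def _build_model(model: str, params: dict, seed: int):
    if model == "knn":
        return KNeighborsClassifier(n_neighbors=params.get("k", 10))
    if model == "nb":
        return GaussianNB()
    if model == "logreg":
        return LogisticRegression(max_iter=params.get("max_iter", 1000),
                                  random_state=seed)
    if model == "tree":
        # shallow default: the tree's deliverable is a short printed
        # discrimination rule, not a maximally grown classifier
        return DecisionTreeClassifier(
            criterion=CRITERION_MAP[params.get("criterion", "infogain")],
            max_depth=params.get("max_depth", 5),
            random_state=seed,
        )
    if model == "forest":
        return RandomForestClassifier(
            criterion=CRITERION_MAP[params.get("criterion", "gini")],
            n_estimators=params.get("n_estimators", 100),
            random_state=seed,
        )
    if model == "svm":
        from sklearn.svm import SVC
        return SVC(kernel=params.get("kernel", "linear"), random_state=seed)
    if model == "mlp":
        from sklearn.neural_network import MLPClassifier
        return MLPClassifier(
            hidden_layer_sizes=params.get("hidden_layer_sizes", (20, 20)),
            max_iter=params.get("max_iter", 1000), random_state=seed,
        )
    raise ValueError(f"unknown model {model!r}")


def train_eval(
    table: FeatureTable,
    model: str = "knn",
    split: SplitSpec = SplitSpec(),
    return_fitted: bool = False,
    **params,
):
    """Fit one classifier on a stratified split and report held-out accuracy.

    The split is stratified on the class label with an explicit seed, so a
    fixed seed and input give an identical report on re-run. When the table
    carries pair groups the split is group-aware (both members of a
    homologous pair stay on the same side), which is automatically
    class-balanced because each pair contributes one row per class. Raises
    if either partition loses a class (re-seed in that case).
    """
    if table.groups is not None:
        splitter = GroupShuffleSplit(n_splits=1, train_size=split.train_frac,
                                     random_state=split.seed)
        train_idx, test_idx = next(splitter.split(table.X, table.y, table.groups))
        X_train, X_test = table.X.iloc[train_idx], table.X.iloc[test_idx]
        y_train, y_test = table.y.iloc[train_idx], table.y.iloc[test_idx]
    else:
        X_train, X_test, y_train, y_test = train_test_split(
            table.X, table.y,
            train_size=split.train_frac,
            stratify=table.y,
            random_state=split.seed,
        )
    for part, name in ((y_train, "train"), (y_test, "test")):
        if part.nunique() < 2:
            raise ValueError(
                f"class missing from the {name} partition; re-run with a "
                f"different seed"
            )
    clf = _build_model(model, params, split.seed)
    clf.fit(X_train.to_numpy(), y_train.to_numpy())
    accuracy = 100.0 * float(clf.score(X_test.to_numpy(), y_test.to_numpy()))
    report = ClassifierReport(
        model=model, hyperparameters=dict(params),
        train_frac=split.train_frac, seed=split.seed,
        accuracy=accuracy, n_train=len(X_train), n_test=len(X_test),
    )
    if return_fitted:
        return report, clf
    return report


# ---------------------------------------------------------------------------
# decision-rule extraction


@dataclass(frozen=True)
class DecisionRule:
    """One root-to-leaf path of a fitted tree: ordered (codon, comparator,
    threshold-%) conditions and the leaf's predicted label."""

    conditions: tuple[tuple[str, str, float], ...]
    label: str


def extract_rules(
    fitted_tree: DecisionTreeClassifier,
    feature_names: list[str],
    class_names: list[str] | None = None,
) -> list[DecisionRule]:
    """Unroll a fitted scikit-learn tree into one rule per leaf.

    A degenerate single-leaf tree yields an empty list with a warning.
    Comparators are half-open: ``<=`` goes left, ``>`` goes right.
    """
    tree = fitted_tree.tree_
    if class_names is None:
        class_names = [str(c) for c in fitted_tree.classes_]
    if tree.node_count == 1:
        log.warning("tree has a single leaf; no discriminating rule to extract")
        return []
    rules: list[DecisionRule] = []

    def walk(node: int, conditions: tuple) -> None:
        if tree.children_left[node] == -1:  # leaf
            label = class_names[int(np.argmax(tree.value[node]))]
            rules.append(DecisionRule(conditions=conditions, label=label))
            return
        feat = feature_names[tree.feature[node]]
        thr = float(tree.threshold[node])
        walk(tree.children_left[node], conditions + ((feat, "≤", thr),))
        walk(tree.children_right[node], conditions + ((feat, ">", thr),))

    walk(0, ())
    return rules


def render_rule(rule: DecisionRule, precision: int = 3) -> str:
    """Render one rule in the discriminatory-rule grammar, e.g.
    ``If % GAC (>8.861] and % AGG (≤1.441] → Non-halophile``."""
    conds = " and ".join(
        f"% {codon} ({op}{threshold:.{precision}f}]"
        for codon, op, threshold in rule.conditions
    )
    return f"If {conds} → {rule.label}"


def render_rules(rules: list[DecisionRule], precision: int = 3) -> str:
    return "\n".join(render_rule(r, precision) for r in rules)


def root_feature(rules: list[DecisionRule]) -> str | None:
    """The feature tested at the root split (first condition of any rule)."""
    if not rules:
        return None
    return rules[0].conditions[0][0]
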