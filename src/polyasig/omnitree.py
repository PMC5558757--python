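"""Omnivariate decision tree: a binary tree whose internal nodes are classifiers.

Internal node slots live in a complete binary heap layout (root = 1, children
of i at 2i and 2i+1, depths 0..max_depth-1).  Each internal node routes a
sample left when it predicts class 0 and right when it predicts class 1; a
slot becomes a leaf when pruned by the genome, its routed data is pure or too
small, or the maximum depth is reached.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

FAMILIES = ("univariate_tree", "neural_net", "random_forest", "multinomial_logistic")

#: Which hyperparameter grid each of the two genome hyperparameter genes
#: addresses, per family (None = gene unused for that family).
FAMILY_GENES: dict[str, tuple[str | None, str | None]] = {
    "univariate_tree": (None, "confidence"),
    "neural_net": ("hidden_units", None),
    "random_forest": ("n_trees", "max_features"),
    "multinomial_logistic": (None, "ridge"),
}

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "univariate_tree": {"confidence": [0.1, 0.25, 0.5]},
    "neural_net": {"hidden_units": [5, 10, 20, 40]},
    "random_forest": {"n_trees": [50, 100, 200, 500],
                      "max_features": ["sqrt", "log2", "all"]},
    "multinomial_logistic": {"ridge": [1e-4, 1e-2, 1.0]},
}

# lower confidence -> heavier cost-complexity pruning of the univariate tree
_CONFIDENCE_TO_CCP_ALPHA = {0.1: 0.02, 0.25: 0.01, 0.5: 0.004}


@dataclass(frozen=True)
class NodeClassifierSpec:
    family: str
    hyperparams: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

    def __hash__(self):
        return hash((self.family, tuple(sorted(self.hyperparams.items()))))


@dataclass
class TreeConfig:
    max_depth: int = 3
    min_node_size: int = 30
    grids: dict[str, dict[str, list]] = field(default_factory=lambda: {
        f: {k: list(v) for k, v in g.items()} for f, g in DEFAULT_GRIDS.items()
    })
    mlp_max_iter: int = 200

    @property
    def n_internal_slots(self) -> int:
        return 2 ** self.max_depth - 1


def derive_seed(*parts) -> int:
    """Stable 32-bit seed from arbitrary parts (ints, bytes, strings)."""
    h = hashlib.sha256()
    for part in parts:
        if isinstance(part, bytes):
            h.update(part)
        else:
            h.update(str(part).encode())
        h.update(b"\x00")
    return int.from_bytes(h.digest()[:4], "big")


class NodeModel:
    """Uniform fit/predict/predict_score wrapper around a node classifier.

    ``predict(x) == (predict_score(x) >= 0.5)`` by construction; deterministic
    for a fixed seed.
    """

    def __init__(self, spec: NodeClassifierSpec, seed: int, config: TreeConfig):
        self.spec = spec
        self.seed = seed
        self.config = config
        self._clf = None
        self._constant: int | None = None

    def _build(self):
        hp = self.spec.hyperparams
        fam = self.spec.family
        if fam == "univariate_tree":
            alpha = _CONFIDENCE_TO_CCP_ALPHA.get(hp.get("confidence", 0.25), 0.01)
            return DecisionTreeClassifier(
                criterion="entropy", ccp_alpha=alpha, random_state=self.seed
            )
        if fam == "neural_net":
            return MLPClassifier(
                hidden_layer_sizes=(hp.get("hidden_units", 10),),
                max_iter=self.config.mlp_max_iter, random_state=self.seed,
            )
        if fam == "random_forest":
            mf = hp.get("max_features", "sqrt")
            return RandomForestClassifier(
                n_estimators=hp.get("n_trees", 100),
                max_features=None if mf == "all" else mf,
                random_state=self.seed, n_jobs=1,
            )
        return LogisticRegression(
            C=1.0 / hp.get("ridge", 1e-2), max_iter=1000, random_state=self.seed
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NodeModel":
        classes = np.unique(y)
        if len(classes) == 1:
            self._constant = int(classes[0])
            return self
        self._clf = self._build()
        with warnings.catch_warnings():
            # unconverged MLP nodes are acceptable candidates; the GA scores
            # them on validation error like any other node
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._clf.fit(X, y)
        return self

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        if self._constant is not None:
            return np.full(len(X), float(self._constant))
        proba = self._clf.predict_proba(X)
        idx = list(self._clf.classes_).index(1)
        return proba[:, idx]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_score(X) >= 0.5).astype(int)


@dataclass
class _Leaf:
    label: int
    score: float  # fraction of class-1 training samples routed here
    n: int


@dataclass
class _Internal:
    spec: NodeClassifierSpec
    model: NodeModel


@dataclass
class OmniTree:
    config: TreeConfig
    nodes: dict[int, _Leaf | _Internal]
    n_features: int

    def is_leaf(self, idx: int) -> bool:
        return isinstance(self.nodes[idx], _Leaf)


def _majority(y: np.ndarray, parent_majority: int) -> tuple[int, float]:
    """(majority label, class-1 fraction); ties fall back to the parent then 1."""
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 > n0:
        label = 1
    elif n0 > n1:
        label = 0
    else:
        label = parent_majority
    return label, n1 / len(y)


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    genome_spec: dict[int, tuple[bool, NodeClassifierSpec | None]],
    seed: int,
    config: TreeConfig | None = None,
) -> OmniTree:
    """Fit an omnivariate tree; each node trains only on the samples routed to it.

    ``genome_spec`` maps heap slot index -> (pruned, NodeClassifierSpec).
    """
    config = config or TreeConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) == 0:
        raise ValueError("empty training set")
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D and aligned with y")
    nodes: dict[int, _Leaf | _Internal] = {}

    def build(idx: int, rows: np.ndarray, depth: int, parent_majority: int,
              parent_score: float) -> None:
        if len(rows) == 0:
            nodes[idx] = _Leaf(label=parent_majority, score=parent_score, n=0)
            return
        y_sub = y[rows]
        label, score = _majority(y_sub, parent_majority)
        pruned, spec = genome_spec.get(idx, (True, None))
        pure = len(np.unique(y_sub)) == 1
        if (pruned or spec is None or depth >= config.max_depth
                or pure or len(rows) < config.min_node_size):
            nodes[idx] = _Leaf(label=label, score=score, n=len(rows))
            return
        model = NodeModel(spec, seed=derive_seed(seed, idx), config=config)
        model.fit(X[rows], y_sub)
        pred = model.predict(X[rows])
        left, right = rows[pred == 0], rows[pred == 1]
        if len(left) == 0 or len(right) == 0:
            # degenerate split: the classifier routes everything one way
            nodes[idx] = _Leaf(label=label, score=score, n=len(rows))
            return
        nodes[idx] = _Internal(spec=spec, model=model)
        build(2 * idx, left, depth + 1, label, score)
        build(2 * idx + 1, right, depth + 1, label, score)

    root_majority, root_score = _majority(y, 1)
    build(1, np.arange(len(y)), 0, root_majority, root_score)
    return OmniTree(config=config, nodes=nodes, n_features=X.shape[1])


def _route(tree: OmniTree, x: np.ndarray) -> _Leaf:
    idx = 1
    while True:
        node = tree.nodes[idx]
        if isinstance(node, _Leaf):
            return node
        branch = int(node.model.predict(x.reshape(1, -1))[0])
        idx = 2 * idx + branch


def predict_tree(tree: OmniTree, X: np.ndarray) -> np.ndarray:
    """Class labels by root-to-leaf traversal."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != tree.n_features:
        raise ValueError(f"expected {tree.n_features} features, got {X.shape[1]}")
    return np.array([_route(tree, x).label for x in X])


def predict_score_tree(tree: OmniTree, X: np.ndarray) -> np.ndarray:
    """Fraction of true-signal training samples at the reached leaf."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != tree.n_features:
        raise ValueError(f"expected {tree.n_features} features, got {X.shape[1]}")
    return np.array([_route(tree, x).score for x in X])
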