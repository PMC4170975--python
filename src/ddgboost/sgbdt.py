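"""Stochastic Gradient Boosting of Decision Trees (least-squares regression).

Implements gradient tree boosting in the classical form: the model starts
from the training-target mean, and each boosting iteration fits a CART
least-squares regression tree to the current residuals on a subsample of the
training set drawn at random *without replacement*, then adds the tree scaled
by a shrinkage factor ν.  Subsampling without replacement makes the training
stochastic, analogous to Random Forests, and acts as a regularizer.

Split search is exhaustive: at each node every feature is scanned over the
midpoints of consecutive sorted unique values and the (feature, threshold)
pair with the largest squared-error reduction is chosen; ties are broken by
the lowest feature index, then the lowest threshold, which together with a
seeded RNG makes training fully deterministic.

Feature importance follows the classical definition: for each feature, sum
the squared-error reduction of every split made on it (weighted by the node
sample count), over all trees; values are reported relative to the most
important feature (= 100).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "TreeNode",
    "SgbdtParams",
    "Ensemble",
    "fit_tree",
    "fit_sgbdt",
    "predict",
    "feature_importance",
    "grid_search",
    "ensemble_to_json",
    "ensemble_from_json",
    "DEFAULT_GRID",
]


@dataclass
class TreeNode:
    """Internal node (feature_index/threshold/children) or leaf (value).

    ``left`` receives samples with ``x[feature_index] <= threshold``.
    ``squared_error_reduction`` is the per-sample impurity decrease of the
    split; multiplied by ``n_samples`` it is the node's SSE reduction.
    """

    value: float | None = None
    feature_index: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    squared_error_reduction: float = 0.0
    n_samples: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.feature_index is None


def _best_split(X: np.ndarray, y: np.ndarray, min_samples_leaf: int):
    """Exhaustive split search.  Returns (sse_reduction, feature, threshold)
    or None.  Ties: lowest feature index, then lowest threshold."""
    n = len(y)
    if n < 2 * min_samples_leaf:
        return None
    total_sum = y.sum()
    total_sse = float(((y - total_sum / n) ** 2).sum())
    best = None
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        # candidate split after position i (1-based left size)
        csum = np.cumsum(ys)
        sizes = np.arange(1, n)
        left_sum = csum[:-1]
        right_sum = total_sum - left_sum
        sq_sum = float((ys ** 2).sum())
        sse_after = sq_sum - left_sum ** 2 / sizes - right_sum ** 2 / (n - sizes)
        reduction = total_sse - sse_after
        valid = (xs[1:] > xs[:-1]) \
            & (sizes >= min_samples_leaf) & ((n - sizes) >= min_samples_leaf)
        if not valid.any():
            continue
        reduction = np.where(valid, reduction, -np.inf)
        k = int(np.argmax(reduction))  # first max -> lowest threshold
        red = float(reduction[k])
        if red <= 1e-12:
            continue
        thr = 0.5 * (xs[k] + xs[k + 1])
        # a later feature must beat the incumbent by more than float noise;
        # exact/near ties keep the lowest feature index
        if best is None or red > best[0] + 1e-9 * max(1.0, abs(best[0])):
            best = (red, j, float(thr))
    return best


def fit_tree(X: np.ndarray, y: np.ndarray, max_depth: int = 3,
             min_samples_leaf: int = 1) -> TreeNode:
    """CART least-squares regression tree fitted by exhaustive split search."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0] or len(y) == 0:
        raise ValueError("X must be 2-D with one target per row")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("X and y must be finite")
    if max_depth < 1 or min_samples_leaf < 1:
        raise ValueError("max_depth and min_samples_leaf must be >= 1")
    return _grow(X, y, max_depth, min_samples_leaf)


def _grow(X, y, depth_left, min_samples_leaf) -> TreeNode:
    node = TreeNode(value=float(y.mean()), n_samples=len(y))
    if depth_left < 1 or len(y) < 2:
        return node
    found = _best_split(X, y, min_samples_leaf)
    if found is None:
        return node
    red, j, thr = found
    mask = X[:, j] <= thr
    node.feature_index = j
    node.threshold = thr
    node.squared_error_reduction = red / len(y)
    node.left = _grow(X[mask], y[mask], depth_left - 1, min_samples_leaf)
    node.right = _grow(X[~mask], y[~mask], depth_left - 1, min_samples_leaf)
    return node


def _tree_predict(node: TreeNode, X: np.ndarray) -> np.ndarray:
    out = np.empty(len(X))
    stack = [(node, np.arange(len(X)))]
    while stack:
        nd, idx = stack.pop()
        if nd.is_leaf:
            out[idx] = nd.value
            continue
        mask = X[idx, nd.feature_index] <= nd.threshold
        stack.append((nd.left, idx[mask]))
        stack.append((nd.right, idx[~mask]))
    return out


@dataclass(frozen=True)
class SgbdtParams:
    n_trees: int = 300
    shrinkage: float = 0.1
    subsample_fraction: float = 0.8
    max_depth: int = 3
    min_samples_leaf: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 0:
            raise ValueError("n_trees must be >= 0")
        if not 0.0 < self.shrinkage <= 1.0:
            raise ValueError("shrinkage must be in (0, 1]")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.max_depth < 1 or self.min_samples_leaf < 1:
            raise ValueError("max_depth and min_samples_leaf must be >= 1")


@dataclass
class Ensemble:
    init_value: float
    trees: list[TreeNode]
    params: SgbdtParams
    feature_names: list[str] | None = None
    n_features: int | None = None
    train_mse_path: list[float] = field(default_factory=list)

    @property
    def importances(self) -> np.ndarray:
        return feature_importance(self)


def fit_sgbdt(X, y, params: SgbdtParams,
              feature_names: list[str] | None = None) -> Ensemble:
    """Fit the boosted ensemble.  Deterministic given ``params.seed``.

    Each iteration m draws ⌈subsample_fraction·n⌉ rows without replacement
    from an RNG seeded with ``seed + m``, fits a tree to the residuals of the
    current model on that subsample, and updates F ← F + ν·tree(X).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be 2-D with one target per row")
    if len(y) < 2:
        raise ValueError("need at least 2 training samples")
    if not np.isfinite(y).all():
        raise ValueError("targets must be finite")
    if feature_names is not None and len(feature_names) != X.shape[1]:
        raise ValueError("feature_names length must match X columns")

    n = len(y)
    m_sub = int(math.ceil(params.subsample_fraction * n))
    f0 = float(y.mean())
    pred = np.full(n, f0)
    trees: list[TreeNode] = []
    mse_path = [float(((y - pred) ** 2).mean())]
    for m in range(params.n_trees):
        rng = np.random.default_rng(params.seed + m)
        idx = np.sort(rng.choice(n, size=m_sub, replace=False))
        resid = y - pred
        tree = fit_tree(X[idx], resid[idx], params.max_depth,
                        params.min_samples_leaf)
        trees.append(tree)
        pred = pred + params.shrinkage * _tree_predict(tree, X)
        mse_path.append(float(((y - pred) ** 2).mean()))
    return Ensemble(init_value=f0, trees=trees, params=params,
                    feature_names=list(feature_names) if feature_names else None,
                    n_features=X.shape[1], train_mse_path=mse_path)


def predict(ensemble: Ensemble, X, feature_names: list[str] | None = None) -> np.ndarray:
    """ΔΔG_DT predictions: init_value + ν·Σ trees(X)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if feature_names is not None and ensemble.feature_names is not None \
            and list(feature_names) != ensemble.feature_names:
        raise ValueError("feature registry mismatch with trained model")
    if ensemble.feature_names is not None and X.shape[1] != len(ensemble.feature_names):
        raise ValueError(f"expected {len(ensemble.feature_names)} features, "
                         f"got {X.shape[1]}")
    out = np.full(len(X), ensemble.init_value)
    for tree in ensemble.trees:
        out = out + ensemble.params.shrinkage * _tree_predict(tree, X)
    return out


def feature_importance(ensemble: Ensemble) -> np.ndarray:
    """Σ over splits of (squared-error reduction × node count), rescaled so
    the most important feature scores 100."""
    if ensemble.trees is None:
        raise RuntimeError("ensemble is not fitted")
    n_feat = ensemble.n_features
    if n_feat is None and ensemble.feature_names is not None:
        n_feat = len(ensemble.feature_names)
    raw: dict[int, float] = {}
    for tree in ensemble.trees:
        stack = [tree]
        while stack:
            nd = stack.pop()
            if nd.is_leaf:
                continue
            raw[nd.feature_index] = raw.get(nd.feature_index, 0.0) + \
                nd.squared_error_reduction * nd.n_samples
            stack.extend([nd.left, nd.right])
    if n_feat is None:
        n_feat = (max(raw) + 1) if raw else 0
    imp = np.zeros(n_feat)
    for j, v in raw.items():
        imp[j] = v
    top = imp.max()
    if top > 0:
        imp = imp * (100.0 / top)
    return imp


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

DEFAULT_GRID = {
    "n_trees": [100, 300, 1000],
    "shrinkage": [0.01, 0.05, 0.1],
    "subsample_fraction": [0.5, 0.8, 1.0],
    "max_depth": [2, 3, 5],
    "min_samples_leaf": [1, 5, 15],
}


def grid_search(X, y, grid: dict, cv_splits, seed: int = 0):
    """Exhaustive hyper-parameter search.

    ``cv_splits`` is an iterable of (train_idx, test_idx) pairs (as produced
    by the evaluation module's schemes).  Selection: highest mean test-fold
    Pearson r; ties broken by lower n_trees, then lower max_depth.  Returns
    (best SgbdtParams, table) where the table lists every setting with its
    mean r.
    """
    from .evaluation import pearson_r

    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty hyper-parameter grid")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    splits = [(np.asarray(tr), np.asarray(te)) for tr, te in cv_splits]
    keys = sorted(grid)
    table = []
    best = None
    for combo in itertools.product(*(grid[k] for k in keys)):
        kwargs = dict(zip(keys, combo))
        params = SgbdtParams(seed=seed, **kwargs)
        rs = []
        for tr, te in splits:
            model = fit_sgbdt(X[tr], y[tr], params)
            pred = predict(model, X[te])
            if len(te) >= 2 and np.std(pred) > 0 and np.std(y[te]) > 0:
                rs.append(pearson_r(pred, y[te]))
        mean_r = float(np.mean(rs)) if rs else float("-inf")
        table.append({**kwargs, "mean_r": mean_r})
        key = (-mean_r, params.n_trees, params.max_depth)
        if best is None or key < best[0]:
            best = (key, params)
    return best[1], table


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _node_to_obj(nd: TreeNode) -> dict:
    if nd.is_leaf:
        return {"value": nd.value, "n": nd.n_samples}
    return {
        "feature_index": nd.feature_index,
        "threshold": nd.threshold,
        "reduction": nd.squared_error_reduction,
        "n": nd.n_samples,
        "left": _node_to_obj(nd.left),
        "right": _node_to_obj(nd.right),
    }


def _node_from_obj(obj: dict) -> TreeNode:
    if "feature_index" not in obj:
        return TreeNode(value=obj["value"], n_samples=obj["n"])
    return TreeNode(
        value=None,
        feature_index=obj["feature_index"],
        threshold=obj["threshold"],
        squared_error_reduction=obj["reduction"],
        n_samples=obj["n"],
        left=_node_from_obj(obj["left"]),
        right=_node_from_obj(obj["right"]),
    )


def ensemble_to_json(ensemble: Ensemble) -> str:
    return json.dumps({
        "init_value": ensemble.init_value,
        "params": asdict(ensemble.params),
        "feature_names": ensemble.feature_names,
        "n_features": ensemble.n_features,
        "trees": [_node_to_obj(t) for t in ensemble.trees],
    })


def ensemble_from_json(text: str) -> Ensemble:
    obj = json.loads(text)
    return Ensemble(
        init_value=obj["init_value"],
        params=SgbdtParams(**obj["params"]),
        feature_names=obj["feature_names"],
        n_features=obj.get("n_features"),
        trees=[_node_from_obj(t) for t in obj["trees"]],
    )
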