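"""Gradient-boosted response classifier and per-patient SHAP attribution matrix.

A binary XGBoost classifier (logistic objective) is trained on the DEG
feature space with responder labels. Per-patient attributions are then
computed with the path-dependent ("tree_path_dependent") variant of TreeSHAP
on the margin (log-odds) scale: for each tree, the value of a feature subset
S is the conditional expectation of the tree output obtained by following
the sample's path at splits on features in S and averaging children by their
training cover (hessian mass) at splits on features outside S. Summing each
tree's Shapley values over its own split features is exact because features
a tree never splits on are null players.

Attributions are accumulated in float64 so that the additive local-accuracy
identity

    base_value + sum_j phi[i, j] = margin(x_i)

holds to numerical precision, and so that single-tree attributions agree
with brute-force subset-enumeration Shapley values to ~1e-12.
:func:`exact_shapley_oracle` provides that independent enumeration for
small feature counts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb

from .cohort_io import ExpressionMatrix


@dataclass(frozen=True)
class GBTParams:
    """Boosting hyperparameters (conservative defaults against overfitting)."""

    max_depth: int = 3
    learning_rate: float = 0.1
    n_rounds: int = 200
    subsample: float = 0.8
    colsample: float = 0.8
    # minimum hessian mass per leaf: forbids splits that isolate a handful of
    # samples, the main channel through which boosting memorizes noisy labels
    min_child_weight: float = 10.0

    def to_xgb(self, seed: int) -> dict:
        return {
            "objective": "binary:logistic",
            "max_depth": self.max_depth,
            "eta": self.learning_rate,
            "subsample": self.subsample,
            "colsample_bytree": self.colsample,
            "min_child_weight": self.min_child_weight,
            "seed": int(seed),
            "nthread": 1,
            "tree_method": "hist",
            "eval_metric": "logloss",
        }


@dataclass
class TreeArrays:
    """Flat arrays for one regression tree (children index -1 marks a leaf)."""

    feature: np.ndarray  # int, -1 at leaves
    threshold: np.ndarray  # float32-valued
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray  # leaf values (0 elsewhere)
    cover: np.ndarray  # training hessian mass per node

    @property
    def used_features(self) -> np.ndarray:
        return np.unique(self.feature[self.feature >= 0])


@dataclass
class BoostedModel:
    """Trained booster plus the metadata attribution needs."""

    booster: xgb.Booster
    feature_names: list[str]
    params: GBTParams
    seed: int
    base_margin: float
    train_logloss: list[float] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        self.booster.save_model(str(path))


def _as_feature_array(model_features: list[str], expr: ExpressionMatrix | np.ndarray) -> np.ndarray:
    if isinstance(expr, ExpressionMatrix):
        if expr.gene_ids != model_features:
            missing = [g for g in model_features if g not in expr.gene_ids]
            if missing:
                raise ValueError(f"model features missing from expression: {missing[:10]}")
            expr = expr.subset_genes(model_features)
        return expr.values.T  # samples x features
    x = np.asarray(expr, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != len(model_features):
        raise ValueError(f"expected {len(model_features)} features, got {x.shape[1]}")
    return x


def train_gbt(
    expr_subset: ExpressionMatrix,
    labels: np.ndarray,
    params: GBTParams | None = None,
    seed: int = 0,
) -> BoostedModel:
    """Train the responder/non-responder classifier on DEG features.

    Deterministic for fixed (inputs, params, seed); stores the per-round
    training log-loss.
    """
    params = params or GBTParams()
    y = np.asarray(labels).astype(int)
    if y.shape != (expr_subset.n_samples,):
        raise ValueError("labels must align with expression samples")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; need both responders and non-responders")
    if np.bincount(y, minlength=2).min() < 2:
        raise ValueError("need at least 2 samples per class")
    X = expr_subset.values.T
    if not np.all(np.isfinite(X)):
        raise ValueError("expression features contain non-finite values")
    dtrain = xgb.DMatrix(X, label=y, feature_names=list(expr_subset.gene_ids))
    history: dict = {}
    booster = xgb.train(
        params.to_xgb(seed),
        dtrain,
        num_boost_round=params.n_rounds,
        evals=[(dtrain, "train")],
        evals_result=history,
        verbose_eval=False,
    )
    cfg = json.loads(booster.save_config())
    base_score = float(cfg["learner"]["learner_model_param"]["base_score"])
    base_margin = float(np.log(base_score / (1.0 - base_score)))
    return BoostedModel(
        booster=booster,
        feature_names=list(expr_subset.gene_ids),
        params=params,
        seed=seed,
        base_margin=base_margin,
        train_logloss=[float(v) for v in history.get("train", {}).get("logloss", [])],
    )


def predict_margin(model: BoostedModel, x: ExpressionMatrix | np.ndarray) -> np.ndarray:
    """Raw log-odds margin per sample; probability is logistic(margin)."""
    X = _as_feature_array(model.feature_names, x)
    dm = xgb.DMatrix(X, feature_names=model.feature_names)
    return model.booster.predict(dm, output_margin=True).astype(float)


def predict_probability(model: BoostedModel, x: ExpressionMatrix | np.ndarray) -> np.ndarray:
    margin = predict_margin(model, x)
    return 1.0 / (1.0 + np.exp(-margin))


# ---------------------------------------------------------------------------
# Tree parsing


def _flatten_dump(node: dict, store: dict) -> None:
    store[node["nodeid"]] = node
    for child in node.get("children", []):
        _flatten_dump(child, store)


def parse_trees(model: BoostedModel) -> list[TreeArrays]:
    """Extract flat tree arrays (with training cover) from the booster."""
    feat_index = {name: i for i, name in enumerate(model.feature_names)}
    trees = []
    for dump in model.booster.get_dump(dump_format="json", with_stats=True):
        nodes: dict = {}
        _flatten_dump(json.loads(dump), nodes)
        ids = sorted(nodes)
        remap = {nid: i for i, nid in enumerate(ids)}
        n = len(ids)
        feature = np.full(n, -1, dtype=int)
        threshold = np.zeros(n)
        left = np.full(n, -1, dtype=int)
        right = np.full(n, -1, dtype=int)
        value = np.zeros(n)
        cover = np.zeros(n)
        for nid in ids:
            node = nodes[nid]
            i = remap[nid]
            cover[i] = node["cover"]
            if "leaf" in node:
                value[i] = node["leaf"]
            else:
                feature[i] = feat_index[node["split"]]
                threshold[i] = np.float32(node["split_condition"])
                left[i] = remap[node["yes"]]
                right[i] = remap[node["no"]]
        trees.append(TreeArrays(feature, threshold, left, right, value, cover))
    return trees


def _tree_expectation_vec(tree: TreeArrays, X32: np.ndarray, in_subset: np.ndarray) -> np.ndarray:
    """Path-dependent expectation of one tree for every sample.

    ``in_subset[f]`` marks features conditioned on (followed by the sample's
    own value); the rest are averaged out by training cover.
    """

    def rec(node: int) -> np.ndarray:
        f = tree.feature[node]
        if f < 0:
            return np.full(X32.shape[0], tree.value[node])
        vl = rec(tree.left[node])
        vr = rec(tree.right[node])
        if in_subset[f]:
            return np.where(X32[:, f] < np.float32(tree.threshold[node]), vl, vr)
        cl = tree.cover[tree.left[node]]
        cr = tree.cover[tree.right[node]]
        return (cl * vl + cr * vr) / (cl + cr)

    return rec(0)


@dataclass
class ShapMatrix:
    """Samples x features additive attributions on the margin scale."""

    phi: np.ndarray
    base_value: float
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("phi shape does not match sample/feature ids")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.phi, index=self.sample_ids, columns=self.feature_ids)

    def write(self, csv_path: str | Path, sidecar_path: str | Path | None = None, meta: dict | None = None) -> None:
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(csv_path)
        if sidecar_path is not None:
            payload = {"base_value": self.base_value}
            if meta:
                payload.update(meta)
            Path(sidecar_path).write_text(json.dumps(payload, indent=2))

    def subset_samples(self, sample_ids: list[str]) -> "ShapMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return ShapMatrix(self.phi[rows], self.base_value, list(self.feature_ids), list(sample_ids))


def shap_matrix(model: BoostedModel, expr_subset: ExpressionMatrix | np.ndarray,
                sample_ids: list[str] | None = None) -> ShapMatrix:
    """Path-dependent TreeSHAP attributions for every sample (float64).

    Per tree, subset values v(S) are enumerated over the tree's own split
    features and combined with Shapley weights; features unused by every
    tree receive exactly 0. Local accuracy: base_value + sum phi equals the
    booster margin per sample.
    """
    X = _as_feature_array(model.feature_names, expr_subset)
    if sample_ids is None:
        sample_ids = (
            list(expr_subset.sample_ids)
            if isinstance(expr_subset, ExpressionMatrix)
            else [f"row{i}" for i in range(X.shape[0])]
        )
    X32 = X.astype(np.float32)
    n, m = X.shape
    phi = np.zeros((n, m))
    base = model.base_margin
    for tree in parse_trees(model):
        feats = tree.used_features
        d = len(feats)
        if d == 0:  # constant tree
            base += float(tree.value[0])
            continue
        pos = {f: i for i, f in enumerate(feats)}
        n_subsets = 1 << d
        v = np.empty((n_subsets, n))
        in_subset = np.zeros(m, dtype=bool)
        for mask in range(n_subsets):
            in_subset[:] = False
            for f, i in pos.items():
                if mask >> i & 1:
                    in_subset[f] = True
            v[mask] = _tree_expectation_vec(tree, X32, in_subset)
        fact = [math.factorial(i) for i in range(d + 1)]
        weight = [fact[s] * fact[d - s - 1] / fact[d] for s in range(d)]
        for f, i in pos.items():
            bit = 1 << i
            col = np.zeros(n)
            for mask in range(n_subsets):
                if mask & bit:
                    continue
                col += weight[int(mask).bit_count()] * (v[mask | bit] - v[mask])
            phi[:, f] += col
        base += float(v[0, 0])  # v(empty set) is sample-constant
    return ShapMatrix(phi=phi, base_value=base, feature_ids=list(model.feature_names), sample_ids=sample_ids)


def local_accuracy_deviation(model: BoostedModel, shap: ShapMatrix, expr_subset) -> float:
    """Max |base_value + sum_j phi_ij - margin_i| over samples."""
    margins = predict_margin(model, expr_subset)
    return float(np.abs(shap.base_value + shap.phi.sum(axis=1) - margins).max())


# ---------------------------------------------------------------------------
# Brute-force Shapley oracle (test reference, independent of shap_matrix)


def _tree_expectation_scalar(tree: TreeArrays, x: np.ndarray, subset: frozenset) -> float:
    def rec(node: int) -> float:
        f = tree.feature[node]
        if f < 0:
            return float(tree.value[node])
        if f in subset:
            child = tree.left[node] if np.float32(x[f]) < np.float32(tree.threshold[node]) else tree.right[node]
            return rec(child)
        cl = tree.cover[tree.left[node]]
        cr = tree.cover[tree.right[node]]
        return (cl * rec(tree.left[node]) + cr * rec(tree.right[node])) / (cl + cr)

    return rec(0)


def exact_shapley_oracle(tree: TreeArrays, x: np.ndarray, n_features: int) -> np.ndarray:
    """Exact Shapley values of one tree by full 2^M subset enumeration.

    The value function is the cover-weighted path-dependent conditional
    expectation over the tree. Refuses more than 10 features.
    """
    if n_features > 10:
        raise ValueError("exact enumeration limited to <= 10 features")
    x = np.asarray(x, dtype=float)
    m = n_features
    fact = [math.factorial(i) for i in range(m + 1)]
    values = {}
    for mask in range(1 << m):
        subset = frozenset(i for i in range(m) if mask >> i & 1)
        values[mask] = _tree_expectation_scalar(tree, x, subset)
    phi = np.zeros(m)
    for j in range(m):
        bit = 1 << j
        for mask in range(1 << m):
            if mask & bit:
                continue
            s = int(mask).bit_count()
            w = fact[s] * fact[m - s - 1] / fact[m]
            phi[j] += w * (values[mask | bit] - values[mask])
    return phi
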