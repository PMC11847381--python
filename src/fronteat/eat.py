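"""Efficiency analysis trees: monotone frontier regression trees.

An efficiency-analysis tree partitions input space R_+^m into half-open boxes
by recursive axis-aligned splits, exactly like a CART regression tree, but
its leaf estimates are output *maxima* rather than means, so the fitted
step function is an upper envelope of the data (a deterministic production
frontier) that is non-decreasing in every input (free disposability).

Growth scores candidate splits by the summed child errors

    R(t) = n(t)/N * MSE(t) = 1/N * sum_{i in t} ||y_i - y(t)||^2,

where the child estimate y(t) is the componentwise maximum of the child's
observed outputs and of the estimates of already-terminal nodes whose
support lower corner is dominated by the child's lower corner (the Pareto
backup that pushes the tree toward a monotone envelope).  After growth (and
after pruning) the leaf estimates are finalized as the minimal monotone
closure of the per-leaf observed maxima over the leaf partition, which makes
the predictor provably non-decreasing while still enveloping every training
observation.

Deep trees are pruned by cost-complexity (weakest-link) pruning with k-fold
cross-validation, selecting the complexity parameter with the smallest
held-out squared error (ties go to the smaller subtree).
"""
from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Node", "Tree", "EATHyperparams", "EATRegressor",
    "best_split", "grow_tree", "prune_tree", "predict",
    "eat_importance", "tune_eat", "ImportanceResult",
]


@dataclass
class EATHyperparams:
    """Tuning knobs: numstop (min node size to attempt a split), CV fold count,
    and optional depth cap (edges from the root; root has depth 0)."""

    numstop: int = 5
    fold: int = 5
    max_depth: int | None = None

    def __post_init__(self) -> None:
        if self.numstop < 2:
            raise ValueError("numstop must be >= 2")
        if self.fold < 2:
            raise ValueError("fold must be >= 2")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1 or None")


@dataclass
class ImportanceResult:
    """Per-input importance scores. ``kind`` records the scoring rule."""

    scores: pd.Series
    kind: str


class Node:
    """One tree node: support box [lo, hi), member observations, split and
    estimates.  ``est``/``R`` are the growth-time estimate and error (used for
    split selection and pruning); ``fest``/``fR`` are the finalized monotone
    leaf estimate and its error (used for prediction)."""

    __slots__ = ("id", "parent", "depth", "obs", "lo", "hi",
                 "split_var", "split_val", "left", "right",
                 "est", "R", "fest", "fR")

    def __init__(self, nid, parent, depth, obs, lo, hi):
        self.id = nid
        self.parent = parent
        self.depth = depth
        self.obs = np.asarray(obs, dtype=np.intp)
        self.lo = np.asarray(lo, dtype=float)
        self.hi = np.asarray(hi, dtype=float)
        self.split_var = None
        self.split_val = None
        self.left = None
        self.right = None
        self.est = None
        self.R = 0.0
        self.fest = None
        self.fR = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def clone(self) -> "Node":
        c = Node(self.id, self.parent, self.depth, self.obs.copy(),
                 self.lo.copy(), self.hi.copy())
        c.split_var, c.split_val = self.split_var, self.split_val
        c.left, c.right = self.left, self.right
        c.est = None if self.est is None else np.asarray(self.est, float).copy()
        c.R = self.R
        c.fest = None if self.fest is None else np.asarray(self.fest, float).copy()
        c.fR = self.fR
        return c


class Tree:
    """An EAT tree: id-indexed nodes, training-size normalizer N, and the
    hyperparameters/metadata of the fit."""

    def __init__(self, nodes: dict[int, Node], N: int, hyperparams: dict | None = None):
        self.nodes = nodes
        self.root = 0
        self.N = int(N)
        self.hyperparams = dict(hyperparams or {})
        self.meta: dict = {}

    # -- structure ---------------------------------------------------------
    def leaves(self) -> list[Node]:
        return [nd for nd in self.nodes.values() if nd.is_leaf]

    def interior(self) -> list[Node]:
        return [nd for nd in self.nodes.values() if not nd.is_leaf]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_leaves(self) -> int:
        return sum(1 for nd in self.nodes.values() if nd.is_leaf)

    @property
    def R_T(self) -> float:
        """Training error: sum of finalized terminal-node errors."""
        return float(sum(nd.fR for nd in self.leaves()))

    # -- prediction --------------------------------------------------------
    def leaf_for(self, x: np.ndarray) -> Node:
        nd = self.nodes[self.root]
        while not nd.is_leaf:
            nd = self.nodes[nd.left] if x[nd.split_var] < nd.split_val else self.nodes[nd.right]
        return nd

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.vstack([self.leaf_for(x).fest for x in X])

    def split_gains(self) -> dict[int, float]:
        """Per-variable total error reduction R(t) - R(t_L) - R(t_R) over splits."""
        gains: dict[int, float] = {}
        for nd in self.interior():
            g = nd.R - (self.nodes[nd.left].R + self.nodes[nd.right].R)
            gains[nd.split_var] = gains.get(nd.split_var, 0.0) + g
        return gains

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def enc(v):
            return None if v is None else np.asarray(v, float).tolist()

        return {
            "N": self.N,
            "hyperparams": self.hyperparams,
            "nodes": [{
                "id": nd.id, "parent": nd.parent, "depth": nd.depth,
                "obs": nd.obs.tolist(), "lo": enc(nd.lo),
                "hi": [None if not np.isfinite(v) else v for v in nd.hi],
                "split_var": nd.split_var, "split_val": nd.split_val,
                "left": nd.left, "right": nd.right,
                "est": enc(nd.est), "R": nd.R, "fest": enc(nd.fest), "fR": nd.fR,
            } for nd in self.nodes.values()],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "Tree":
        nodes = {}
        for d in payload["nodes"]:
            hi = [np.inf if v is None else v for v in d["hi"]]
            nd = Node(d["id"], d["parent"], d["depth"], d["obs"], d["lo"], hi)
            nd.split_var, nd.split_val = d["split_var"], d["split_val"]
            nd.left, nd.right = d["left"], d["right"]
            nd.est = None if d["est"] is None else np.asarray(d["est"], float)
            nd.R = d["R"]
            nd.fest = None if d["fest"] is None else np.asarray(d["fest"], float)
            nd.fR = d["fR"]
            nodes[nd.id] = nd
        return cls(nodes, payload["N"], payload.get("hyperparams"))


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

def _node_error(Y: np.ndarray, obs: np.ndarray, est: np.ndarray, N: int) -> float:
    return float(((Y[obs] - est) ** 2).sum() / N)


def _backup_estimate(lo: np.ndarray, terminals: Iterable[Node], exclude_id: int):
    """Max estimate over terminal nodes whose support lower corner is
    componentwise <= ``lo`` (Pareto backup), or None if there is none."""
    out = None
    for t in terminals:
        if t.id == exclude_id:
            continue
        if np.all(t.lo <= lo):
            out = t.est if out is None else np.maximum(out, t.est)
    return out


def _best_split_node(node: Node, X: np.ndarray, Y: np.ndarray, N: int,
                     terminals: Sequence[Node], allowed: Sequence[int]):
    """Exhaustively score candidate splits (j, s) with s among the observed
    values of x_j in the node; left child takes {x_j < s}.  Returns
    (err_sum, j, s, left_obs, right_obs, est_L, est_R, R_L, R_R) or None."""
    obs = node.obs
    Xo = X[obs]
    best = None
    for j in sorted(int(v) for v in allowed):
        vals = np.unique(Xo[:, j])
        if vals.size < 2:
            continue
        col = Xo[:, j]
        for s in vals[1:]:  # splitting at the minimum would empty the left child
            lmask = col < s
            lobs, robs = obs[lmask], obs[~lmask]
            lo_r = node.lo.copy()
            lo_r[j] = s
            est_l = Y[lobs].max(axis=0)
            b = _backup_estimate(node.lo, terminals, node.id)
            if b is not None:
                est_l = np.maximum(est_l, b)
            est_r = Y[robs].max(axis=0)
            b = _backup_estimate(lo_r, terminals, node.id)
            if b is not None:
                est_r = np.maximum(est_r, b)
            est_r = np.maximum(est_r, est_l)  # the fresh left leaf also backs up the right
            r_l = _node_error(Y, lobs, est_l, N)
            r_r = _node_error(Y, robs, est_r, N)
            err = r_l + r_r
            if best is None or err < best[0] - 1e-12 * (1.0 + abs(best[0])):
                best = (err, j, float(s), lobs, robs, est_l, est_r, r_l, r_r)
    return best


def _finalize(tree: Tree, Y: np.ndarray) -> None:
    """Set final leaf estimates to the minimal monotone closure of per-leaf
    observed maxima: fest(t) >= fest(t') whenever some point of t' is
    dominated by some point of t (equivalently lo(t') < hi(t) componentwise).
    Guarantees a monotone predictor that envelopes every observation."""
    leaves = tree.leaves()
    for t in leaves:
        t.fest = Y[t.obs].max(axis=0).astype(float)
    los = np.vstack([t.lo for t in leaves])
    his = np.vstack([t.hi for t in leaves])
    # dominates[a, b]: leaf b's estimate must be >= leaf a's
    dominates = np.all(los[:, None, :] < his[None, :, :], axis=2)
    np.fill_diagonal(dominates, False)
    changed = True
    while changed:
        changed = False
        for b, t in enumerate(leaves):
            src = np.flatnonzero(dominates[:, b])
            if src.size == 0:
                continue
            cand = np.maximum(t.fest, np.vstack([leaves[a].fest for a in src]).max(axis=0))
            if np.any(cand > t.fest):
                t.fest = cand
                changed = True
    for t in leaves:
        t.fR = _node_error(Y, t.obs, t.fest, tree.N)


def _grow(X: np.ndarray, Y: np.ndarray, *,
          stop: Callable[[int], bool],
          max_depth: int | None = None,
          allowed_vars: Sequence[int] | None = None,
          mtry_fn: Callable[[int], int] | None = None,
          rng: np.random.Generator | None = None,
          hyperparams: dict | None = None) -> Tree:
    n, m = X.shape
    root = Node(0, None, 0, np.arange(n), np.zeros(m), np.full(m, np.inf))
    root.est = Y.max(axis=0).astype(float)
    root.R = _node_error(Y, root.obs, root.est, n)
    nodes = {0: root}
    terminals = {0: root}
    queue = deque([root])
    next_id = 1
    base_allowed = np.arange(m) if allowed_vars is None else np.asarray(sorted(allowed_vars))
    while queue:
        nd = queue.popleft()
        if stop(len(nd.obs)):
            continue
        if max_depth is not None and nd.depth >= max_depth:
            continue
        if mtry_fn is not None:
            k = min(mtry_fn(len(nd.obs)), len(base_allowed))
            allowed = rng.choice(base_allowed, size=k, replace=False)
        else:
            allowed = base_allowed
        res = _best_split_node(nd, X, Y, n, list(terminals.values()), allowed)
        if res is None:
            continue
        _, j, s, lobs, robs, est_l, est_r, r_l, r_r = res
        left = Node(next_id, nd.id, nd.depth + 1, lobs, nd.lo.copy(), nd.hi.copy())
        left.hi[j] = s
        right_lo = nd.lo.copy()
        right_lo[j] = s
        right = Node(next_id + 1, nd.id, nd.depth + 1, robs, right_lo, nd.hi.copy())
        left.est, left.R = np.asarray(est_l, float), r_l
        right.est, right.R = np.asarray(est_r, float), r_r
        nd.split_var, nd.split_val = j, s
        nd.left, nd.right = left.id, right.id
        nodes[left.id] = left
        nodes[right.id] = right
        del terminals[nd.id]
        terminals[left.id] = left
        terminals[right.id] = right
        queue.append(left)
        queue.append(right)
        next_id += 2
    tree = Tree(nodes, n, hyperparams)
    _finalize(tree, Y)
    return tree


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def _effective_leaves(tree: Tree, collapsed: set[int], nid: int) -> list[int]:
    out, stack = [], [nid]
    while stack:
        i = stack.pop()
        nd = tree.nodes[i]
        if nd.is_leaf or i in collapsed:
            out.append(i)
        else:
            stack.extend((nd.left, nd.right))
    return out


def _weakest_link(tree: Tree, collapsed: set[int]):
    """Min link strength g(t) and its minimizers among current interior nodes."""
    best, argbest = None, []
    for nd in tree.interior():
        if nd.id in collapsed:
            continue
        # skip nodes hidden under a collapsed ancestor
        p = nd.parent
        hidden = False
        while p is not None:
            if p in collapsed:
                hidden = True
                break
            p = tree.nodes[p].parent
        if hidden:
            continue
        leaf_ids = _effective_leaves(tree, collapsed, nd.id)
        if len(leaf_ids) <= 1:
            continue
        r_sub = sum(tree.nodes[i].R for i in leaf_ids)
        g = (nd.R - r_sub) / (len(leaf_ids) - 1)
        if best is None or g < best - 1e-12 * (1.0 + abs(best)):
            best, argbest = g, [nd.id]
        elif g <= best + 1e-12 * (1.0 + abs(best)):
            argbest.append(nd.id)
    return best, argbest


def _alpha_sequence(tree: Tree) -> list[float]:
    collapsed: set[int] = set()
    alphas: list[float] = []
    while True:
        g, ids = _weakest_link(tree, collapsed)
        if g is None:
            break
        alphas.append(max(g, 0.0))
        collapsed.update(ids)
    # enforce monotone non-decreasing sequence
    out, cur = [], 0.0
    for a in alphas:
        cur = max(cur, a)
        out.append(cur)
    return out


def _collapse_at(tree: Tree, alpha: float) -> set[int]:
    collapsed: set[int] = set()
    while True:
        g, ids = _weakest_link(tree, collapsed)
        if g is None or g > alpha + 1e-12 * (1.0 + abs(alpha)):
            break
        collapsed.update(ids)
    return collapsed


def _pruned_copy(tree: Tree, collapsed: set[int], Y: np.ndarray) -> Tree:
    nodes: dict[int, Node] = {}
    stack = [tree.root]
    while stack:
        i = stack.pop()
        nd = tree.nodes[i].clone()
        if i in collapsed:
            nd.split_var = nd.split_val = nd.left = nd.right = None
        elif not nd.is_leaf:
            stack.extend((nd.left, nd.right))
        nodes[i] = nd
    out = Tree(nodes, tree.N, tree.hyperparams)
    out.meta = dict(tree.meta)
    _finalize(out, Y)
    return out


def prune_tree(tree: Tree, X: np.ndarray, Y: np.ndarray, fold: int,
               rng_seed: int = 0) -> Tree:
    """Cost-complexity pruning with ``fold``-fold cross-validation.

    Builds the weakest-link subtree sequence of ``tree``, evaluates each
    representative complexity parameter by regrowing on every training fold
    and scoring held-out squared error, and returns the subtree for the
    parameter with the smallest CV error (ties resolved toward the smaller
    subtree).
    """
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.reshape(X.shape[0], -1)
    n = X.shape[0]
    if fold > n:
        raise ValueError("fold must not exceed the number of observations")
    if tree.n_leaves <= 1:
        return _pruned_copy(tree, set(), Y)

    alphas = sorted(set(_alpha_sequence(tree)))
    reps = [0.0]
    for k, a in enumerate(alphas):
        if k + 1 < len(alphas):
            reps.append(math.sqrt(max(a, 0.0) * alphas[k + 1]))
        else:
            reps.append(a)
    reps = sorted(set(reps))

    hp = tree.hyperparams
    numstop = hp.get("numstop", 2)
    max_depth = hp.get("max_depth")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, fold)
    cv_err = {r: 0.0 for r in reps}
    for held in folds:
        mask = np.ones(n, dtype=bool)
        mask[held] = False
        sub = _grow(X[mask], Y[mask], stop=lambda nt: nt < numstop,
                    max_depth=max_depth, hyperparams=hp)
        for r in reps:
            pruned = _pruned_copy(sub, _collapse_at(sub, r), Y[mask])
            pred = pruned.predict(X[held])
            cv_err[r] += float(((Y[held] - pred) ** 2).sum())

    best_r, best_e = None, None
    for r in reps:  # ascending; "<=" keeps the largest alpha (smallest subtree) on ties
        e = cv_err[r]
        if best_e is None or e <= best_e + 1e-12 * (1.0 + abs(best_e)):
            if best_e is None or e < best_e - 1e-12 * (1.0 + abs(best_e)):
                best_e = e
            best_r = r
    out = _pruned_copy(tree, _collapse_at(tree, best_r), Y)
    out.meta.update({
        "cv_alpha": best_r, "cv_seed": rng_seed, "fold": fold,
        "cv_error_by_alpha": {float(r): float(cv_err[r]) for r in reps},
        "cv_fold_assignment": [np.sort(f).tolist() for f in folds],
    })
    return out


# ---------------------------------------------------------------------------
# scikit-learn style estimator
# ---------------------------------------------------------------------------

def _as_xy(X, y):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    Y = y[:, None] if single else y
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and y have inconsistent numbers of rows")
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("X and y must not contain NaN")
    return X, Y, single


class EATRegressor:
    """Monotone frontier tree with a scikit-learn fit/predict interface.

    Parameters
    ----------
    numstop : minimum node size for a split to be attempted.
    fold : number of cross-validation folds used by cost-complexity pruning.
    max_depth : optional cap on tree depth (edges from the root).
    prune : whether to apply CV cost-complexity pruning after growth.
    random_state : seed for the pruning fold assignment.
    """

    def __init__(self, numstop: int = 5, fold: int = 5, max_depth: int | None = None,
                 prune: bool = True, random_state: int | None = None):
        self.numstop = numstop
        self.fold = fold
        self.max_depth = max_depth
        self.prune = prune
        self.random_state = random_state

    # minimal get_params/set_params so the estimator composes with sklearn tooling
    def get_params(self, deep: bool = True) -> dict:
        return {"numstop": self.numstop, "fold": self.fold,
                "max_depth": self.max_depth, "prune": self.prune,
                "random_state": self.random_state}

    def set_params(self, **params) -> "EATRegressor":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "EATRegressor":
        EATHyperparams(self.numstop, self.fold, self.max_depth)  # validate
        X, Y, self._single_output = _as_xy(X, y)
        hp = {"numstop": self.numstop, "fold": self.fold, "max_depth": self.max_depth}
        tree = _grow(X, Y, stop=lambda nt: nt < self.numstop,
                     max_depth=self.max_depth, hyperparams=hp)
        if self.prune and tree.n_leaves > 1:
            seed = 0 if self.random_state is None else int(self.random_state)
            tree = prune_tree(tree, X, Y, self.fold, seed)
        self.tree_ = tree
        self.n_features_in_ = X.shape[1]
        gains = tree.split_gains()
        g = np.array([gains.get(j, 0.0) for j in range(X.shape[1])])
        tot = g.sum()
        self.feature_importances_ = g / tot if tot > 0 else g
        return self

    def predict(self, X) -> np.ndarray:
        pred = self.tree_.predict(X)
        return pred[:, 0] if self._single_output else pred

    def score(self, X, y) -> float:
        """Negative mean squared error (higher is better)."""
        pred = np.atleast_2d(self.predict(X).reshape(len(np.atleast_2d(X)), -1))
        Y = np.asarray(y, float).reshape(pred.shape)
        return -float(((Y - pred) ** 2).mean())


# ---------------------------------------------------------------------------
# module-level functional wrappers
# ---------------------------------------------------------------------------

def best_split(node: Node, dmus, allowed_vars, tree: Tree):
    """Best (variable, threshold, error-sum) for ``node`` against the current
    terminal set of ``tree``; None when no candidate yields two nonempty
    children."""
    res = _best_split_node(node, dmus.X, dmus.Y, tree.N,
                           tree.leaves(), list(allowed_vars))
    if res is None:
        return None
    err, j, s = res[0], res[1], res[2]
    return j, s, err


def grow_tree(dmus, hp: EATHyperparams, allowed_vars=None, rng_seed: int = 0) -> Tree:
    hpd = {"numstop": hp.numstop, "fold": hp.fold, "max_depth": hp.max_depth}
    return _grow(dmus.X, dmus.Y, stop=lambda nt: nt < hp.numstop,
                 max_depth=hp.max_depth, allowed_vars=allowed_vars, hyperparams=hpd)


def predict(tree: Tree, x) -> np.ndarray:
    return tree.predict(np.atleast_2d(np.asarray(x, float)))[0]


def eat_importance(dmus, hp: EATHyperparams, rng_seed: int = 0,
                   tree: Tree | None = None) -> ImportanceResult:
    """EAT variable importance: per-variable total MSE reduction across the
    (pruned) tree's splits, rescaled so the largest score is exactly 100."""
    if tree is None:
        grown = grow_tree(dmus, hp)
        tree = prune_tree(grown, dmus.X, dmus.Y, hp.fold, rng_seed)
    gains = tree.split_gains()
    g = np.array([max(gains.get(j, 0.0), 0.0) for j in range(dmus.m)])
    names = getattr(dmus, "input_names", [f"x{j + 1}" for j in range(dmus.m)])
    if g.max() <= 0:
        if not gains:
            warnings.warn("tree has no splits; all importances reported as 0")
        scores = pd.Series(np.zeros(dmus.m), index=names)
    else:
        scores = pd.Series((g / g.max()) * 100.0, index=names)
    return ImportanceResult(scores=scores, kind="eat_mse_reduction")


def tune_eat(dmus, grid: Sequence[EATHyperparams], rng_seed: int = 0):
    """Grid search by k-fold cross-validated RMSE of the pruned-tree predictor.

    For each hyperparameter combination the data are split into ``fold``
    folds; a tree is grown and pruned on each training part and scored on the
    held-out part.  Returns (best combo, RMSE table); ties prefer smaller
    numstop, then smaller max_depth.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    X, Y = dmus.X, dmus.Y
    n = X.shape[0]
    rows = []
    for hp in grid:
        rng = np.random.default_rng(rng_seed)
        perm = rng.permutation(n)
        folds = np.array_split(perm, hp.fold)
        sse, cnt = 0.0, 0
        for held in folds:
            mask = np.ones(n, dtype=bool)
            mask[held] = False
            est = EATRegressor(hp.numstop, hp.fold, hp.max_depth,
                               random_state=rng_seed).fit(X[mask], Y[mask])
            pred = est.tree_.predict(X[held])
            sse += float(((Y[held] - pred) ** 2).sum())
            cnt += held.size * Y.shape[1]
        rows.append({"numstop": hp.numstop, "fold": hp.fold,
                     "max_depth": hp.max_depth, "rmse": math.sqrt(sse / cnt)})
    table = pd.DataFrame(rows)
    order = sorted(
        range(len(grid)),
        key=lambda i: (rows[i]["rmse"], rows[i]["numstop"],
                       math.inf if rows[i]["max_depth"] is None else rows[i]["max_depth"],
                       rows[i]["fold"]),
    )
    return grid[order[0]], table
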