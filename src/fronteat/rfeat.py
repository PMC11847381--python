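"""Random forests of efficiency-analysis trees.

RFEAT replaces the pruning step of a single EAT tree with dual
randomization: p bootstrap resamples of the data (each of size n, drawn with
replacement) grow unpruned trees whose splits consider a fresh random subset
of input variables, and the forest frontier is the average of the tree
predictors,

    y_hat(x) = 1/p * sum_q d_{T(sample_q)}(x).

Because each tree only envelopes its own bootstrap sample, the averaged
frontier need not envelope every observation — efficiency scores below 1
flag strongly efficient DMUs.  Out-of-bag (OOB) bookkeeping provides honest
generalization error (squared error summed over outputs and averaged over
observations that are out of bag at least once) and permutation variable
importance (%Inc: percentage increase of OOB error when one input column is
randomly permuted).
"""
from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .eat import ImportanceResult, Tree, _grow

__all__ = [
    "MTRY_RULES", "mtry_count", "RFEATRegressor",
    "fit_forest", "forest_predict", "oob_error_curve",
    "rfeat_importance", "tune_rfeat",
]

MTRY_RULES = ("BREIMAN", "DEA1", "DEA2", "DEA3", "DEA4")


def mtry_count(rule: str, m: int, s: int, n_t: int) -> int:
    """Number of candidate split variables for one split.

    BREIMAN uses m/3; the DEA rules depend on the parent node size n(t):
    DEA1 = n(t)/2 - s, DEA2 = n(t)/3 - s, DEA3 = n(t)/(2s),
    DEA4 = min{n(t)/s, n(t)/3 - s}.  All values are floored, then clamped
    to [1, m].
    """
    rule = str(rule).upper()
    if rule == "BREIMAN":
        k = m / 3
    elif rule == "DEA1":
        k = n_t / 2 - s
    elif rule == "DEA2":
        k = n_t / 3 - s
    elif rule == "DEA3":
        k = n_t / (2 * s)
    elif rule == "DEA4":
        k = min(n_t / s, n_t / 3 - s)
    else:
        raise ValueError(f"unknown mtry rule {rule!r}; expected one of {MTRY_RULES}")
    return int(np.clip(math.floor(k), 1, m))


class RFEATRegressor:
    """Bagged ensemble of unpruned EAT trees with randomized variable subsets.

    Parameters
    ----------
    n_estimators : number of trees p.
    n_min : stopping rule — a node with n(t) <= n_min is terminal.
    mtry : one of ``MTRY_RULES`` (case-insensitive).
    random_state : master seed; all bootstrap and variable-subset draws are
        derived from it, so identical seeds give bit-identical forests.
    """

    def __init__(self, n_estimators: int = 500, n_min: int = 7,
                 mtry: str = "BREIMAN", random_state: int | None = None):
        self.n_estimators = n_estimators
        self.n_min = n_min
        self.mtry = mtry
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"n_estimators": self.n_estimators, "n_min": self.n_min,
                "mtry": self.mtry, "random_state": self.random_state}

    def set_params(self, **params) -> "RFEATRegressor":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "RFEATRegressor":
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        X = np.atleast_2d(np.asarray(X, float))
        yarr = np.asarray(y, float)
        self._single_output = yarr.ndim == 1
        Y = yarr[:, None] if self._single_output else yarr
        n, m = X.shape
        s = Y.shape[1]
        seed = 0 if self.random_state is None else int(self.random_state)
        master = np.random.default_rng(np.random.SeedSequence(seed))
        self.estimators_: list[Tree] = []
        inbag = np.zeros((self.n_estimators, n), dtype=bool)
        self.bootstrap_indices_ = []
        for q in range(self.n_estimators):
            idx = master.integers(0, n, size=n)
            tree_rng = np.random.default_rng(int(master.integers(0, 2 ** 31)))
            tree = _grow(
                X[idx], Y[idx],
                stop=lambda nt: nt <= self.n_min,
                mtry_fn=lambda nt: mtry_count(self.mtry, m, s, nt),
                rng=tree_rng,
            )
            self.estimators_.append(tree)
            self.bootstrap_indices_.append(idx)
            inbag[q, idx] = True
        self._inbag = inbag
        self.oob_sets_ = [np.flatnonzero(~inbag[:, i]) for i in range(n)]
        self._X, self._Y = X, Y
        self.n_features_in_ = m
        # per-tree predictions at the training points, reused by OOB bookkeeping
        self._train_pred = np.stack([t.predict(X) for t in self.estimators_])  # (p, n, s)
        curve = self.oob_error_curve()
        self.oob_error_ = float(curve[-1][1]) if curve else float("nan")
        return self

    # -- prediction --------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        pred = np.mean([t.predict(X) for t in self.estimators_], axis=0)
        return pred[:, 0] if self._single_output else pred

    # -- OOB ---------------------------------------------------------------
    def _oob_error_from(self, preds: np.ndarray) -> float:
        """Mean over observations with nonempty OOB set of the squared error
        of the OOB-averaged prediction (summed over outputs)."""
        mask = ~self._inbag  # (p, n)
        w = mask[:, :, None].astype(float)
        den = w.sum(axis=0)  # (n, 1)
        has = den[:, 0] > 0
        if not has.any():
            return float("nan")
        avg = (preds * w).sum(axis=0)[has] / den[has]
        return float((((self._Y[has] - avg) ** 2).sum(axis=1)).mean())

    def oob_error_curve(self) -> list[tuple[int, float]]:
        """Running OOB error over tree-count prefixes q = 1..p.

        For each prefix, an observation's OOB prediction averages the trees in
        its OOB set restricted to the prefix; observations never OOB within
        the prefix are excluded from that prefix's mean.
        """
        mask = (~self._inbag)[:, :, None].astype(float)  # (p, n, 1)
        num = np.cumsum(self._train_pred * mask, axis=0)
        den = np.cumsum(mask, axis=0)
        curve = []
        for q in range(self.n_estimators):
            has = den[q, :, 0] > 0
            if not has.any():
                curve.append((q + 1, float("nan")))
                continue
            avg = num[q, has] / den[q, has]
            err = float((((self._Y[has] - avg) ** 2).sum(axis=1)).mean())
            curve.append((q + 1, err))
        return curve

    def oob_excluded_count(self) -> int:
        """Observations that are never out of bag (in every bootstrap sample)."""
        return int((self._inbag.all(axis=0)).sum())

    # -- permutation importance --------------------------------------------
    def permutation_importance(self, random_state: int | None = None,
                               feature_names: Sequence[str] | None = None) -> ImportanceResult:
        """%Inc per input: percentage increase in OOB error after randomly
        permuting that input column (predictions from the fitted trees at the
        permuted points; the trees are not refit)."""
        err0 = self.oob_error_
        names = list(feature_names) if feature_names is not None else \
            [f"x{j + 1}" for j in range(self.n_features_in_)]
        if not np.isfinite(err0) or err0 == 0:
            warnings.warn("baseline OOB error is zero or undefined; %Inc is undefined")
            return ImportanceResult(
                scores=pd.Series(np.full(self.n_features_in_, np.nan), index=names),
                kind="rfeat_pct_inc")
        rng = np.random.default_rng(0 if random_state is None else int(random_state))
        n = self._X.shape[0]
        pct = np.empty(self.n_features_in_)
        for j in range(self.n_features_in_):
            Xp = self._X.copy()
            Xp[:, j] = self._X[rng.permutation(n), j]
            preds = np.stack([t.predict(Xp) for t in self.estimators_])
            errj = self._oob_error_from(preds)
            pct[j] = 100.0 * (errj - err0) / err0
        return ImportanceResult(scores=pd.Series(pct, index=names), kind="rfeat_pct_inc")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "params": self.get_params(),
            "single_output": self._single_output,
            "X": self._X.tolist(), "Y": self._Y.tolist(),
            "bootstrap_indices": [idx.tolist() for idx in self.bootstrap_indices_],
            "trees": [t.to_dict() for t in self.estimators_],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RFEATRegressor":
        est = cls(**payload["params"])
        est._single_output = payload["single_output"]
        est._X = np.asarray(payload["X"], float)
        est._Y = np.asarray(payload["Y"], float)
        est.estimators_ = [Tree.from_dict(d) for d in payload["trees"]]
        est.bootstrap_indices_ = [np.asarray(i, dtype=np.intp)
                                  for i in payload["bootstrap_indices"]]
        n = est._X.shape[0]
        inbag = np.zeros((len(est.estimators_), n), dtype=bool)
        for q, idx in enumerate(est.bootstrap_indices_):
            inbag[q, idx] = True
        est._inbag = inbag
        est.oob_sets_ = [np.flatnonzero(~inbag[:, i]) for i in range(n)]
        est.n_features_in_ = est._X.shape[1]
        est._train_pred = np.stack([t.predict(est._X) for t in est.estimators_])
        curve = est.oob_error_curve()
        est.oob_error_ = float(curve[-1][1]) if curve else float("nan")
        return est


# ---------------------------------------------------------------------------
# module-level functional wrappers
# ---------------------------------------------------------------------------

def fit_forest(dmus, p: int, n_min: int, rule: str, rng_seed: int = 0) -> RFEATRegressor:
    return RFEATRegressor(n_estimators=p, n_min=n_min, mtry=rule,
                          random_state=rng_seed).fit(dmus.X, dmus.Y)


def forest_predict(forest: RFEATRegressor, x) -> np.ndarray:
    pred = forest.predict(np.atleast_2d(np.asarray(x, float)))
    return np.atleast_1d(pred[0]) if np.ndim(pred) else pred


def oob_error_curve(forest: RFEATRegressor, dmus=None) -> list[tuple[int, float]]:
    return forest.oob_error_curve()


def rfeat_importance(forest: RFEATRegressor, dmus=None, rng_seed: int = 0) -> ImportanceResult:
    names = getattr(dmus, "input_names", None) if dmus is not None else None
    return forest.permutation_importance(random_state=rng_seed, feature_names=names)


def tune_rfeat(dmus, grid, rng_seed: int = 0):
    """Grid search over (n_min, p, rule) by OOB RMSE (sqrt of the forest's
    final OOB error).  Ties prefer smaller p, then smaller n_min."""
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    rows = []
    for n_min, p, rule in grid:
        forest = RFEATRegressor(n_estimators=p, n_min=n_min, mtry=rule,
                                random_state=rng_seed).fit(dmus.X, dmus.Y)
        rows.append({"n_min": n_min, "p": p, "rule": rule,
                     "oob_rmse": math.sqrt(forest.oob_error_)})
    table = pd.DataFrame(rows)
    order = sorted(range(len(grid)),
                   key=lambda i: (rows[i]["oob_rmse"], rows[i]["p"], rows[i]["n_min"]))
    return grid[order[0]], table
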