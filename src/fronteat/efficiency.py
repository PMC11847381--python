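"""Output-oriented VRS efficiency scoring against EAT and RFEAT technologies.

For a fitted EAT tree, the technology is the set under the tree frontier,
and the mixed-integer radial program (a one-hot selection lambda over
terminal nodes, feasible when the node's support lower corner a^t is
dominated by the DMU's inputs) reduces to leaf enumeration:

    phi_k = max_{t : a^t <= x_k} min_r d_r(a^t) / y_rk .

Leaves at the input-space origin are feasible for every DMU, and the DMU's
own leaf is always feasible, so phi_k >= 1.  The RFEAT score uses the
averaged forest frontier directly, phi_k = min_r y_hat_r(x_k) / y_rk, and
may fall below 1 because the forest does not envelope all observations.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eat import Tree
from .fdh import FDHScores

__all__ = ["EfficiencyResult", "eat_efficiency", "rfeat_efficiency",
           "score_table", "competition_rank"]

MODELS = ("fdh", "eat", "rfeat")


@dataclass
class EfficiencyResult:
    """Combined per-DMU score table plus mean/SD summary and fit metadata.

    ``table`` columns follow the dmu_id, phi_*, rec_*, rank_* layout; ranks
    are competition ranks on reciprocals rounded to 3 decimals (printed
    granularity) and ``rank_*_unrounded`` keeps the tie-free variant.
    """

    table: pd.DataFrame
    summary: pd.DataFrame
    meta: dict = field(default_factory=dict)


def competition_rank(values: np.ndarray, descending: bool = True) -> np.ndarray:
    """Competition ("min") ranking: ties share the smallest rank and the next
    distinct value skips by the tie count."""
    s = pd.Series(np.asarray(values, float))
    return s.rank(method="min", ascending=not descending).astype(int).to_numpy()


def eat_efficiency(tree: Tree, dmus):
    """Per-DMU phi against the EAT technology, with the peer leaf realizing
    the optimum (lowest leaf id on ties)."""
    leaves = sorted(tree.leaves(), key=lambda nd: nd.id)
    A = np.vstack([nd.lo for nd in leaves])            # (L, m) support lower corners
    D = np.vstack([nd.fest for nd in leaves])          # (L, s) frontier at the corners
    X, Y = np.atleast_2d(dmus.X), np.atleast_2d(dmus.Y)
    feas = np.all(A[None, :, :] <= X[:, None, :], axis=2)          # (n, L)
    ratios = (D[None, :, :] / Y[:, None, :]).min(axis=2)           # (n, L)
    masked = np.where(feas, ratios, -np.inf)
    phi = masked.max(axis=1)
    peer_leaf = np.array([leaves[i].id for i in masked.argmax(axis=1)])
    return phi, peer_leaf


def rfeat_efficiency(forest, dmus) -> np.ndarray:
    """phi_k = min_r y_hat_r(x_k)/y_rk; values below 1 flag strongly
    efficient DMUs.  ``forest`` is any object with a ``predict`` method."""
    X, Y = np.atleast_2d(dmus.X), np.atleast_2d(dmus.Y)
    pred = np.asarray(forest.predict(X), float).reshape(Y.shape[0], -1)
    return (pred / Y).min(axis=1)


def score_table(dmus, fdh_scores: FDHScores, eat_phis, rfeat_phis,
                meta: dict | None = None, round_decimals: int = 3) -> EfficiencyResult:
    """Assemble the combined table with reciprocals and competition ranks.

    Ranks are computed on reciprocals rounded to ``round_decimals`` before
    tie detection (matching printed granularity); unrounded ranks are also
    emitted.
    """
    phis = {"fdh": np.asarray(fdh_scores.phi, float),
            "eat": np.asarray(eat_phis, float),
            "rfeat": np.asarray(rfeat_phis, float)}
    n = len(dmus.dmu_ids)
    for name, v in phis.items():
        if v.shape[0] != n:
            raise ValueError(f"{name} scores length {v.shape[0]} != n = {n}")

    table = pd.DataFrame({"dmu_id": dmus.dmu_ids})
    for name, phi in phis.items():
        rec = 1.0 / phi
        table[f"phi_{name}"] = phi
        table[f"rec_{name}"] = rec
        table[f"rank_{name}"] = competition_rank(np.round(rec, round_decimals))
        table[f"rank_{name}_unrounded"] = competition_rank(rec)

    rows = []
    for stat in ("mean", "sd"):
        row = {"stat": stat}
        for name, phi in phis.items():
            agg = np.mean if stat == "mean" else lambda v: np.std(v, ddof=1)
            row[f"phi_{name}"] = float(agg(phi))
            row[f"rec_{name}"] = float(agg(1.0 / phi))
        rows.append(row)
    summary = pd.DataFrame(rows)
    return EfficiencyResult(table=table, summary=summary, meta=dict(meta or {}))
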