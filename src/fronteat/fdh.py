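"""Free disposal hull: output-oriented efficiency under variable returns to scale.

The FDH technology is the free-disposal closure of the observed data points:
a DMU k can be benchmarked against any observed peer j whose inputs are
weakly smaller in every coordinate.  The output-oriented score is

    phi_k = max_{j : x_j <= x_k} min_r y_rj / y_rk,

the largest radial expansion of k's outputs that stays inside the hull.
Since k dominates itself, phi_k >= 1, with phi_k = 1 for frontier DMUs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FDHScores", "FDHFrontier", "fdh_output_efficiency"]


@dataclass
class FDHScores:
    """Per-DMU radial scores (phi >= 1) with the dominating peer of each DMU."""

    phi: np.ndarray
    peer: np.ndarray  # index of the maximizing peer (lowest index on ties)
    dmu_ids: list[str] | None = None

    @property
    def peer_ids(self) -> list[str] | None:
        if self.dmu_ids is None:
            return None
        return [self.dmu_ids[j] for j in self.peer]


class FDHFrontier:
    """Memorizing estimator of the free-disposal output envelope.

    ``predict`` returns, per output, the maximum observed output among
    training DMUs whose inputs are dominated by the query point (the FDH
    step frontier for s = 1).  Points dominating no observation fall back to
    the componentwise minimum observed output.
    """

    def __init__(self):
        pass

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "FDHFrontier":
        if params:
            raise ValueError(f"invalid parameters {sorted(params)}")
        return self

    def fit(self, X, y) -> "FDHFrontier":
        X = np.atleast_2d(np.asarray(X, float))
        y = np.asarray(y, float)
        self._single_output = y.ndim == 1
        self.X_ = X
        self.Y_ = y[:, None] if self._single_output else y
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        feas = np.all(self.X_[None, :, :] <= X[:, None, :], axis=2)  # (q, n)
        out = np.empty((X.shape[0], self.Y_.shape[1]))
        fallback = self.Y_.min(axis=0)
        for i, mask in enumerate(feas):
            out[i] = self.Y_[mask].max(axis=0) if mask.any() else fallback
        return out[:, 0] if self._single_output else out


def fdh_output_efficiency(dmus) -> FDHScores:
    """Output-oriented VRS FDH scores by dominance enumeration.

    Dominance uses exact weak inequalities (no tolerance); peer ties are
    broken toward the lowest DMU index.
    """
    X = np.atleast_2d(np.asarray(dmus.X, float))
    Y = np.atleast_2d(np.asarray(dmus.Y, float))
    if (Y <= 0).any():
        raise ValueError("outputs must be strictly positive")
    dom = np.all(X[None, :, :] <= X[:, None, :], axis=2)      # dom[k, j]: x_j <= x_k
    ratios = (Y[None, :, :] / Y[:, None, :]).min(axis=2)      # min_r y_rj / y_rk
    masked = np.where(dom, ratios, -np.inf)
    phi = masked.max(axis=1)
    peer = masked.argmax(axis=1)
    return FDHScores(phi=phi, peer=peer, dmu_ids=getattr(dmus, "dmu_ids", None))
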