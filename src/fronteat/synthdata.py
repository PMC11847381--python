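"""Synthetic DMU tables for exercising the frontier pipeline.

Two generators:

* :func:`gen_oecd_like` draws a country-panel-like table from truncated
  normal marginals matched to published summary moments (mean, SD, min, max
  per indicator for 36 OECD members), with a mild positive rank coupling
  between per-capita GDP and the spending indicators through a shared
  Gaussian latent factor.
* :func:`gen_known_frontier` draws inputs uniformly from a box and produces
  outputs from a known monotone frontier f(x) = a + b * prod_j x_j^alpha_j
  with one-sided half-normal inefficiency, y = f(x) * exp(-|N(0, sigma_u)|),
  the standard deterministic-frontier noise model.  The true frontier values
  are returned alongside so recovery error is measurable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import DMUTable

__all__ = ["MomentColumn", "MomentSpec", "FrontierSpec", "OECD_MOMENTS",
           "gen_oecd_like", "gen_known_frontier", "frontier_recovery_metrics"]


@dataclass
class MomentColumn:
    name: str
    mean: float
    sd: float
    vmin: float
    vmax: float
    role: str  # input | output | grouping

    def __post_init__(self) -> None:
        if not (self.vmin <= self.mean <= self.vmax):
            raise ValueError(f"{self.name}: need min <= mean <= max")
        if self.sd < 0:
            raise ValueError(f"{self.name}: SD must be >= 0")


@dataclass
class MomentSpec:
    columns: list[MomentColumn]
    n: int = 36

    def __post_init__(self) -> None:
        roles = [c.role for c in self.columns]
        if "input" not in roles or "output" not in roles:
            raise ValueError("spec needs at least one input and one output column")


# Summary moments of the 36-country OECD health-system table (five-year
# averages 2017-2021 for inputs; life expectancy and the grouping variables
# at their single reference years).
OECD_MOMENTS = MomentSpec(n=36, columns=[
    MomentColumn("medical_spending_pc", 4321, 2154, 1123, 10638, "input"),
    MomentColumn("public_health_share", 6.39, 1.87, 2.85, 9.35, "input"),
    MomentColumn("gdp_pc", 47201, 19653, 15515, 120461, "input"),
    MomentColumn("ner", 92.85, 5.35, 73.16, 99.48, "input"),
    MomentColumn("health_spending_gdp", 9.05, 2.38, 4.32, 17.23, "input"),
    MomentColumn("life_expectancy", 80.31, 3.21, 73.10, 84.50, "output"),
    MomentColumn("oop_pc", 735.44, 302.88, 181.51, 1865.82, "grouping"),
    MomentColumn("old_ratio", 18.01, 4.60, 7.90, 28.90, "grouping"),
])

# indicators coupled to the shared latent wealth factor
_COUPLED = {"gdp_pc", "medical_spending_pc", "health_spending_gdp", "oop_pc"}
_COUPLING_RHO = 0.5


def gen_oecd_like(spec: MomentSpec = OECD_MOMENTS, seed: int = 0) -> DMUTable:
    """Draw a DMU table with truncated-normal marginals matched to ``spec``.

    Each column is an inverse-CDF transform of a standard normal, truncated
    to [min, max]; wealth-linked columns share a latent factor (rank
    correlation ~ ``_COUPLING_RHO``).  Pure function of (spec, seed).
    """
    rng = np.random.default_rng(seed)
    n = spec.n
    factor = rng.standard_normal(n)
    data = {}
    for col in spec.columns:
        z = rng.standard_normal(n)
        if col.name in _COUPLED:
            z = _COUPLING_RHO * factor + np.sqrt(1 - _COUPLING_RHO ** 2) * z
        if col.sd < 1e-12:
            vals = np.full(n, col.mean)
        else:
            a = (col.vmin - col.mean) / col.sd
            b = (col.vmax - col.mean) / col.sd
            u = stats.norm.cdf(z)
            vals = stats.truncnorm.ppf(u, a, b, loc=col.mean, scale=col.sd)
            vals = np.clip(vals, col.vmin, col.vmax)
        data[col.name] = vals

    ids = [f"DMU{i + 1:02d}" for i in range(n)]
    inputs = [c.name for c in spec.columns if c.role == "input"]
    outputs = [c.name for c in spec.columns if c.role == "output"]
    groupings = [c.name for c in spec.columns if c.role == "grouping"]
    groups = pd.DataFrame({g: data[g] for g in groupings}) if groupings else None
    return DMUTable(
        dmu_ids=ids,
        X=np.column_stack([data[v] for v in inputs]),
        Y=np.column_stack([data[v] for v in outputs]),
        input_names=inputs, output_names=outputs, groups=groups,
    )


@dataclass
class FrontierSpec:
    """Known monotone frontier f(x) = intercept + scale * prod_j x_j^alpha_j
    on a uniform input box, with half-normal inefficiency scale sigma_u."""

    n: int = 50
    m: int = 2
    intercept: float = 2.0
    scale: float = 1.0
    alphas: tuple | None = None
    sigma_u: float = 0.1
    box: tuple[float, float] = (1.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alphas is None:
            self.alphas = tuple([0.4] * self.m)
        if len(self.alphas) != self.m:
            raise ValueError("alphas length must equal m")
        if any(a < 0 for a in self.alphas) or self.scale < 0 or self.intercept < 0:
            raise ValueError("frontier must be monotone: alphas, scale, intercept >= 0")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")
        if self.box[0] < 0 or self.box[1] <= self.box[0]:
            raise ValueError("box must satisfy 0 <= lo < hi")

    def frontier(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return self.intercept + self.scale * np.prod(X ** np.asarray(self.alphas), axis=1)


def gen_known_frontier(spec: FrontierSpec) -> tuple[DMUTable, np.ndarray]:
    """Sample (DMUTable, true frontier values).

    Recipe (all from one seeded generator, in order): X ~ U(box)^{n x m},
    u = |N(0, sigma_u)| per DMU, y = f(x) * exp(-u).
    """
    rng = np.random.default_rng(spec.seed)
    X = rng.uniform(spec.box[0], spec.box[1], size=(spec.n, spec.m))
    u = np.abs(rng.normal(0.0, spec.sigma_u, size=spec.n)) if spec.sigma_u > 0 \
        else np.zeros(spec.n)
    truth = spec.frontier(X)
    y = truth * np.exp(-u)
    table = DMUTable(
        dmu_ids=[f"SIM{i + 1:03d}" for i in range(spec.n)],
        X=X, Y=y[:, None],
        input_names=[f"x{j + 1}" for j in range(spec.m)],
        output_names=["y"],
    )
    return table, truth


def frontier_recovery_metrics(predictor, truth: np.ndarray, dmus: DMUTable):
    """(MSE, mean signed bias) of a frontier predictor against the truth,
    evaluated at the table's input points.  ``predictor`` is a callable or an
    object with ``predict``."""
    fn = predictor.predict if hasattr(predictor, "predict") else predictor
    pred = np.asarray(fn(dmus.X), float).reshape(-1)
    truth = np.asarray(truth, float).reshape(-1)
    if pred.shape != truth.shape:
        raise ValueError("predictor output and truth have different lengths")
    diff = pred - truth
    return float((diff ** 2).mean()), float(diff.mean())
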