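"""Indicator-panel ingestion and DMU table construction.

A decision making unit (DMU) — here typically a country — consumes m
nonnegative inputs to produce s strictly positive outputs.  The analysis
window is a contiguous range of years (default 2017-2021): inputs and
grouping variables are averaged over the years with available values, the
output is taken at a designated year (with nearest-year fallback inside the
window), and a DMU is dropped only when an input series is missing for the
whole window.  Every exclusion or imputation is recorded in the table's
provenance so the construction is auditable.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

ROLES = ("input", "output", "grouping")
_LONG_COLUMNS = {"dmu_id", "year", "variable", "value"}


class PanelFormatError(ValueError):
    """Malformed panel CSV or schema."""


class PanelIntegrityError(ValueError):
    """Duplicate (dmu_id, year, variable) records."""


@dataclass
class IndicatorPanel:
    """Long-form (dmu_id, year, variable, value) records plus variable roles."""

    records: pd.DataFrame
    roles: dict[str, str]

    def __post_init__(self) -> None:
        dup = self.records.duplicated(subset=["dmu_id", "year", "variable"])
        if dup.any():
            row = self.records[dup].iloc[0]
            raise PanelIntegrityError(
                f"duplicate record for ({row['dmu_id']}, {row['year']}, {row['variable']})"
            )
        unknown = set(self.records["variable"]) - set(self.roles)
        if unknown:
            raise PanelFormatError(f"variables without a declared role: {sorted(unknown)}")
        bad = set(self.roles.values()) - set(ROLES)
        if bad:
            raise PanelFormatError(f"unknown roles {sorted(bad)}; expected one of {ROLES}")
        if not self.variables("input") or not self.variables("output"):
            raise PanelFormatError("schema must declare at least one input and one output")

    def variables(self, role: str) -> list[str]:
        return sorted(v for v, r in self.roles.items() if r == role)


@dataclass
class DMUTable:
    """The dataset: n DMUs with input matrix X (n x m) and output matrix Y (n x s).

    Inputs must be nonnegative and outputs strictly positive (output-oriented
    scores divide by observed outputs).  ``groups`` carries grouping variables
    (may contain missing values); ``provenance`` records exclusions and
    imputations applied during construction.
    """

    dmu_ids: list[str]
    X: np.ndarray
    Y: np.ndarray
    input_names: list[str]
    output_names: list[str]
    groups: pd.DataFrame | None = None
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if self.Y.ndim == 1:
            self.Y = self.Y[:, None]
        self.validate()

    def validate(self) -> None:
        n = len(self.dmu_ids)
        if n < 1:
            raise ValueError("DMUTable requires at least one DMU")
        if self.X.shape != (n, len(self.input_names)):
            raise ValueError("X shape does not match dmu_ids/input_names")
        if self.Y.shape != (n, len(self.output_names)):
            raise ValueError("Y shape does not match dmu_ids/output_names")
        if self.X.shape[1] < 1 or self.Y.shape[1] < 1:
            raise ValueError("need at least one input and one output")
        if np.isnan(self.X).any() or np.isnan(self.Y).any():
            raise ValueError("X and Y must not contain missing values")
        if (self.X < 0).any():
            raise ValueError("inputs must be nonnegative")
        if (self.Y <= 0).any():
            raise ValueError("outputs must be strictly positive")

    @property
    def n(self) -> int:
        return len(self.dmu_ids)

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def s(self) -> int:
        return self.Y.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"dmu_id": self.dmu_ids})
        for j, name in enumerate(self.input_names):
            df[f"in:{name}"] = self.X[:, j]
        for r, name in enumerate(self.output_names):
            df[f"out:{name}"] = self.Y[:, r]
        if self.groups is not None:
            for name in self.groups.columns:
                df[f"gv:{name}"] = np.asarray(self.groups[name])
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DMUTable":
        """Rebuild a table from the role-prefixed wide CSV written by :meth:`to_frame`."""
        ins = [c for c in df.columns if c.startswith("in:")]
        outs = [c for c in df.columns if c.startswith("out:")]
        gvs = [c for c in df.columns if c.startswith("gv:")]
        if not ins or not outs:
            raise PanelFormatError("DMU CSV needs 'in:' and 'out:' prefixed columns")
        groups = None
        if gvs:
            groups = df[gvs].copy()
            groups.columns = [c[3:] for c in gvs]
            groups.index = range(len(df))
        return cls(
            dmu_ids=[str(v) for v in df["dmu_id"]],
            X=df[ins].to_numpy(float),
            Y=df[outs].to_numpy(float),
            input_names=[c[3:] for c in ins],
            output_names=[c[3:] for c in outs],
            groups=groups,
        )


def _load_schema(schema) -> dict[str, str]:
    if isinstance(schema, (str, Path)):
        with open(schema, "r", encoding="utf-8") as fh:
            schema = yaml.safe_load(fh)
    if not isinstance(schema, dict):
        raise PanelFormatError("schema must be a mapping of variable -> role")
    roles = schema.get("roles", schema)
    out = {}
    for var, role in roles.items():
        if isinstance(role, dict):  # allow {variable: {role: ..., unit: ...}}
            role = role.get("role")
        out[str(var)] = str(role).lower()
    return out


def load_panel(path, schema) -> IndicatorPanel:
    """Read a long- or wide-form indicator CSV into a validated panel.

    Long form has exactly the columns (dmu_id, year, variable, value); any
    other layout is treated as wide form with one column per variable.  Blank
    cells become missing values; non-numeric cells raise a parse error naming
    the offending row.
    """
    roles = _load_schema(schema)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - delegated to pandas
        raise PanelFormatError(f"could not parse CSV {path}: {exc}") from exc

    if _LONG_COLUMNS.issubset(df.columns):
        long = df[list(_LONG_COLUMNS)].copy()
    else:
        if "dmu_id" not in df.columns or "year" not in df.columns:
            raise PanelFormatError("wide panel needs 'dmu_id' and 'year' columns")
        value_cols = [c for c in df.columns if c not in ("dmu_id", "year")]
        long = df.melt(
            id_vars=["dmu_id", "year"], value_vars=value_cols,
            var_name="variable", value_name="value",
        )
    long["dmu_id"] = long["dmu_id"].astype(str)
    try:
        long["year"] = long["year"].astype(int)
    except (TypeError, ValueError) as exc:
        raise PanelFormatError(f"non-integer year in panel: {exc}") from exc

    raw = long["value"]
    parsed = pd.to_numeric(raw, errors="coerce")
    bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        row = long.iloc[i]
        raise PanelFormatError(
            f"non-numeric value {raw.iloc[i]!r} at row {i} "
            f"({row['dmu_id']}, {row['year']}, {row['variable']})"
        )
    long["value"] = parsed
    long = long[["dmu_id", "year", "variable", "value"]].reset_index(drop=True)
    return IndicatorPanel(records=long, roles=roles)


def _nearest_year(avail: pd.Series, target: int) -> int:
    """Year in ``avail.index`` closest to ``target``; ties go to the later year."""
    years = np.asarray(sorted(avail.index))
    dist = np.abs(years - target)
    best = dist.min()
    return int(years[dist == best].max())


def build_dmu_table(
    panel: IndicatorPanel,
    window: tuple[int, int] = (2017, 2021),
    output_year: int = 2021,
) -> DMUTable:
    """Average inputs/grouping variables over the window and pick the output year.

    A DMU is excluded (with a provenance note) when any input variable is
    missing for every window year, or when the output is missing for the whole
    window (the latter also emits a warning).  A missing output at
    ``output_year`` is imputed from the nearest available in-window year,
    breaking ties toward the more recent year.
    """
    lo, hi = int(window[0]), int(window[1])
    if hi < lo:
        raise ValueError("empty analysis window")
    if not (lo <= output_year <= hi):
        raise ValueError("output_year must lie inside the analysis window")

    rec = panel.records
    rec = rec[(rec["year"] >= lo) & (rec["year"] <= hi)]
    inputs = panel.variables("input")
    outputs = panel.variables("output")
    groupings = panel.variables("grouping")

    provenance: list[dict] = []
    rows: list[dict] = []
    cube = rec.pivot_table(
        index=["dmu_id", "variable"], columns="year", values="value", aggfunc="first"
    )

    for dmu in sorted(rec["dmu_id"].unique()):
        row: dict = {"dmu_id": dmu}
        ok = True
        for var in inputs + groupings:
            try:
                series = cube.loc[(dmu, var)].dropna()
            except KeyError:
                series = pd.Series(dtype=float)
            if series.empty:
                if var in inputs:
                    provenance.append({
                        "dmu_id": dmu, "variable": var,
                        "rule": "excluded", "detail": "input missing for all window years",
                    })
                    ok = False
                    break
                row[var] = np.nan
                provenance.append({
                    "dmu_id": dmu, "variable": var,
                    "rule": "grouping_missing", "detail": "no window values",
                })
                continue
            row[var] = float(series.mean())
            if len(series) < hi - lo + 1:
                provenance.append({
                    "dmu_id": dmu, "variable": var, "rule": "partial_average",
                    "detail": f"averaged over {len(series)} of {hi - lo + 1} years",
                })
        if not ok:
            continue
        for var in outputs:
            try:
                series = cube.loc[(dmu, var)].dropna()
            except KeyError:
                series = pd.Series(dtype=float)
            if series.empty:
                warnings.warn(f"DMU {dmu} excluded: output {var} missing in every window year")
                provenance.append({
                    "dmu_id": dmu, "variable": var,
                    "rule": "excluded", "detail": "output missing for all window years",
                })
                ok = False
                break
            if output_year in series.index:
                row[var] = float(series[output_year])
            else:
                year = _nearest_year(series, output_year)
                row[var] = float(series[year])
                provenance.append({
                    "dmu_id": dmu, "variable": var, "rule": "nearest_year_output",
                    "detail": f"output taken from {year} instead of {output_year}",
                })
        if ok:
            rows.append(row)

    if not rows:
        raise ValueError("no DMU survived exclusion rules; empty table")

    df = pd.DataFrame(rows)
    groups = df[groupings].copy() if groupings else None
    return DMUTable(
        dmu_ids=list(df["dmu_id"]),
        X=df[inputs].to_numpy(float),
        Y=df[outputs].to_numpy(float),
        input_names=inputs,
        output_names=outputs,
        groups=groups,
        provenance=provenance,
    )
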