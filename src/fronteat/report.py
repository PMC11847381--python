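"""Downstream analytics over efficiency results.

Covers: the degree to which FDH underestimates inefficiency relative to a
reference model, correlation tables of scores and rankings across models,
group comparisons of reciprocal scores (continents or quartile bins of a
numeric grouping variable), kernel-density comparison of the reciprocal
score distributions, and CSV/Markdown table rendering.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .eat import Tree
from .efficiency import MODELS, EfficiencyResult

__all__ = [
    "underestimation_degree", "underestimation_table", "correlation_report",
    "GroupSummary", "group_summary", "density_compare",
    "node_summary_table", "terminal_summary_table", "render_tables",
]


# ---------------------------------------------------------------------------
# underestimation
# ---------------------------------------------------------------------------

def underestimation_degree(phi_fdh, phi_ref):
    """Percentage by which FDH understates inefficiency relative to a
    reference model: ((1/phi_FDH) - (1/phi_ref)) / (1/phi_ref) * 100,
    algebraically (phi_ref/phi_fdh - 1) * 100."""
    phi_fdh = np.asarray(phi_fdh, float)
    phi_ref = np.asarray(phi_ref, float)
    if (phi_fdh <= 0).any() or (phi_ref <= 0).any():
        raise ValueError("efficiency scores must be positive")
    rec_f, rec_r = 1.0 / phi_fdh, 1.0 / phi_ref
    out = (rec_f - rec_r) / rec_r * 100.0
    return float(out) if out.ndim == 0 else out


def underestimation_table(result: EfficiencyResult) -> pd.DataFrame:
    t = result.table
    return pd.DataFrame({
        "dmu_id": t["dmu_id"],
        "vs_eat_pct": underestimation_degree(t["phi_fdh"], t["phi_eat"]),
        "vs_rfeat_pct": underestimation_degree(t["phi_fdh"], t["phi_rfeat"]),
    })


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def _pair_corr(frame: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    vals = frame[cols].to_numpy(float)
    k = len(cols)
    out = np.full((k, k), np.nan)
    for a in range(k):
        for b in range(k):
            va, vb = vals[:, a], vals[:, b]
            if np.std(va) == 0 or np.std(vb) == 0:
                if a != b:
                    warnings.warn(f"zero-variance column among {cols[a]}, {cols[b]}; "
                                  "correlation undefined")
                out[a, b] = 1.0 if a == b else np.nan
            else:
                out[a, b] = np.corrcoef(va, vb)[0, 1]
    labels = [c.split("_", 1)[1] for c in cols]
    return pd.DataFrame(out, index=labels, columns=labels)


def correlation_report(result: EfficiencyResult) -> dict[str, pd.DataFrame]:
    """Pairwise correlations across the three models.

    ``scores``: Pearson correlation of the phi vectors. ``ranks``: Pearson
    correlation of the printed competition-rank vectors.  ``ranks_spearman``
    adds the average-rank (standard Spearman) variant on reciprocals for
    comparison.
    """
    t = result.table
    scores = _pair_corr(t, [f"phi_{m}" for m in MODELS])
    ranks = _pair_corr(t, [f"rank_{m}" for m in MODELS])
    k = len(MODELS)
    sp = np.full((k, k), np.nan)
    for a in range(k):
        for b in range(k):
            if a == b:
                sp[a, b] = 1.0
                continue
            va = t[f"rec_{MODELS[a]}"]
            vb = t[f"rec_{MODELS[b]}"]
            if np.std(va) == 0 or np.std(vb) == 0:
                continue
            sp[a, b] = stats.spearmanr(va, vb).statistic
    return {"scores": scores, "ranks": ranks,
            "ranks_spearman": pd.DataFrame(sp, index=list(MODELS), columns=list(MODELS))}


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupSummary:
    grouping: str
    table: pd.DataFrame  # columns: group, n, mean_rec_rfeat, sd_rec_rfeat


def _quartile_bins(values: np.ndarray, bins: int) -> np.ndarray:
    """Equal-count bins by the (n+1)-quantile convention; a value equal to a
    cut goes to the lower bin so ties stay together."""
    qs = np.arange(1, bins) / bins
    cuts = np.quantile(values, qs, method="weibull")
    return np.searchsorted(cuts, values, side="left")


def group_summary(result: EfficiencyResult, dmus, grouping: str,
                  bins: int = 4, labels: dict[str, str] | None = None) -> GroupSummary:
    """Per-group n, mean and SD of reciprocal RFEAT scores.

    ``grouping`` is either a column of ``dmus.groups`` (numeric: quartile
    bins) or an arbitrary name used with a ``labels`` map dmu_id -> group
    (e.g. continents).  DMUs without a label go to an "unassigned" group.
    """
    t = result.table
    rec = t["rec_rfeat"].to_numpy(float)
    if labels is not None:
        assignment = [labels.get(d, "unassigned") for d in t["dmu_id"]]
    else:
        if dmus.groups is None or grouping not in dmus.groups.columns:
            raise ValueError(f"grouping variable {grouping!r} not present")
        vals = np.asarray(dmus.groups[grouping], float)
        assignment = []
        ok = ~np.isnan(vals)
        binned = np.full(len(vals), -1)
        if ok.any():
            binned[ok] = _quartile_bins(vals[ok], bins)
        for b in binned:
            assignment.append("unassigned" if b < 0 else f"Q{b + 1}")
    df = pd.DataFrame({"group": assignment, "rec": rec})
    agg = df.groupby("group", sort=True)["rec"].agg(
        n="size", mean_rec_rfeat="mean",
        sd_rec_rfeat=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
    ).reset_index()
    return GroupSummary(grouping=grouping, table=agg)


# ---------------------------------------------------------------------------
# density comparison
# ---------------------------------------------------------------------------

def density_compare(result: EfficiencyResult, grid_size: int = 512,
                    window: tuple[float, float] = (0.999, 1.001)) -> dict:
    """Gaussian-kernel densities (Silverman bandwidth) of reciprocal scores
    per model on a shared grid, with each model's peak location and the
    probability mass inside ``window`` (the mass "at 1")."""
    t = result.table
    recs = {m: t[f"rec_{m}"].to_numpy(float) for m in MODELS}
    allv = np.concatenate(list(recs.values()))
    span = max(allv.max() - allv.min(), 1e-3)
    grid = np.linspace(allv.min() - 0.25 * span, allv.max() + 0.25 * span, grid_size)
    out: dict = {"grid": grid, "models": {}}
    for m, v in recs.items():
        if np.std(v) == 0:
            mass = 1.0 if window[0] <= v[0] <= window[1] else 0.0
            out["models"][m] = {"density": None, "peak": float(v[0]),
                                "mass_at_one": mass, "degenerate": True}
            continue
        kde = stats.gaussian_kde(v, bw_method="silverman")
        dens = kde(grid)
        out["models"][m] = {
            "density": dens,
            "peak": float(grid[int(np.argmax(dens))]),
            "mass_at_one": float(kde.integrate_box_1d(window[0], window[1])),
            "degenerate": False,
        }
    return out


# ---------------------------------------------------------------------------
# table rendering
# ---------------------------------------------------------------------------

def node_summary_table(tree: Tree, dmus) -> pd.DataFrame:
    """Per-node output summary statistics (all nodes, root first): n, share
    of observations, mean/var/quartiles of the first output, and RMSE of the
    node's growth-time estimate."""
    rows = []
    n_total = tree.N
    for nid in sorted(tree.nodes):
        nd = tree.nodes[nid]
        y = np.atleast_2d(dmus.Y)[nd.obs, 0]
        est = nd.fest if nd.is_leaf and nd.fest is not None else nd.est
        rmse = float(np.sqrt(((np.atleast_2d(dmus.Y)[nd.obs] - est) ** 2).mean()))
        rows.append({
            "node": nid + 1, "n": len(nd.obs),
            "pct": round(100.0 * len(nd.obs) / n_total, 1),
            "mean": round(float(y.mean()), 2),
            "var": round(float(y.var(ddof=1)) if len(y) > 1 else 0.0, 2),
            "min": round(float(y.min()), 2),
            "q1": round(float(np.quantile(y, 0.25)), 2),
            "median": round(float(np.quantile(y, 0.5)), 2),
            "q3": round(float(np.quantile(y, 0.75)), 2),
            "max": round(float(y.max()), 2),
            "rmse": round(rmse, 2),
        })
    return pd.DataFrame(rows)


def terminal_summary_table(tree: Tree, dmus) -> pd.DataFrame:
    """Terminal-node summary: id, n, share, frontier estimate, error R(t),
    member DMU ids; a TOTAL row carries the summed error R(T)."""
    rows = []
    for nd in sorted(tree.leaves(), key=lambda v: v.id):
        rows.append({
            "node": str(nd.id + 1), "n": len(nd.obs),
            "pct": round(100.0 * len(nd.obs) / tree.N, 1),
            "frontier_estimate": round(float(nd.fest[0]), 2),
            "R_t": round(float(nd.fR), 2),
            "members": " ".join(dmus.dmu_ids[i] for i in nd.obs),
        })
    frame = pd.DataFrame(rows)
    return _with_total(frame)


def _with_total(frame: pd.DataFrame) -> pd.DataFrame:
    total = {c: "" for c in frame.columns}
    total["node"] = "TOTAL"
    total["n"] = int(frame["n"].sum()) if len(frame) else 0
    total["R_t"] = round(float(pd.to_numeric(frame["R_t"]).sum()), 2) if len(frame) else 0.0
    return pd.concat([frame, pd.DataFrame([total])], ignore_index=True)


def _to_markdown(df: pd.DataFrame) -> str:
    cols = [str(c) for c in df.columns]
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row.to_list()) + " |")
    return "\n".join(lines) + "\n"


def render_tables(results: dict, out_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Render whatever upstream artifacts are present into tidy tables.

    Recognized keys in ``results``: ``tree`` + ``dmus`` (node and terminal
    summaries), ``terminal_summary`` (a pre-built terminal frame, re-rendered
    with a TOTAL row), ``scores`` (EfficiencyResult), ``correlations``,
    ``groups`` (list of GroupSummary).  Empty input yields empty artifacts
    with headers.  When ``out_dir`` is given every table is written as CSV
    and Markdown.
    """
    out: dict[str, pd.DataFrame] = {}
    if "tree" in results and "dmus" in results:
        out["node_summary"] = node_summary_table(results["tree"], results["dmus"])
        out["terminal_summary"] = terminal_summary_table(results["tree"], results["dmus"])
    if "terminal_summary" in results:
        frame = results["terminal_summary"].copy()
        frame = frame[frame["node"].astype(str) != "TOTAL"]
        out["terminal_summary"] = _with_total(frame)
    if "scores" in results:
        res = results["scores"]
        tbl = res.table.copy()
        for c in tbl.columns:
            if c.startswith(("phi_", "rec_")):
                tbl[c] = tbl[c].round(3)
        out["scores"] = tbl
        out["score_summary"] = res.summary.round(3)
        out["underestimation"] = underestimation_table(res).round(3)
    if "correlations" in results:
        for name, frame in results["correlations"].items():
            out[f"correlation_{name}"] = frame.round(4)
    if "groups" in results:
        for gs in results["groups"]:
            out[f"group_{gs.grouping}"] = gs.table.round(4)
    if not out:
        out["terminal_summary"] = pd.DataFrame(
            columns=["node", "n", "pct", "frontier_estimate", "R_t", "members"])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, frame in out.items():
            plain = frame.index.equals(pd.RangeIndex(len(frame)))
            towrite = frame if plain else frame.reset_index(names="model")
            towrite.to_csv(out_dir / f"{name}.csv", index=False)
            (out_dir / f"{name}.md").write_text(_to_markdown(towrite))
    return out
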