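"""Bundled reference fixtures.

Two small tables transcribed from a published 36-country OECD health-system
efficiency comparison are shipped for regression testing and for worked
examples: the per-country output-oriented VRS scores under FDH, EAT and
RFEAT (with reciprocals and competition ranks as printed, 3 decimals), and
the terminal-node summary of the fitted efficiency-analysis tree (node
errors R(t) and ISO 3166-1 alpha-3 member lists).  The underlying
country-level indicator panel is not redistributable, so these printed
results are the only real-data artifacts in the package.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_efficiency_reference", "load_terminal_node_reference"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("fronteat.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_efficiency_reference() -> pd.DataFrame:
    """36-country score table: phi, reciprocal and competition rank for each
    of FDH, EAT and RFEAT (columns phi_*, rec_*, rank_*)."""
    return _read("oecd36_efficiency_reference.csv")


def load_terminal_node_reference() -> pd.DataFrame:
    """Terminal-node summary of the reference 15-node tree (8 leaves):
    node id, size, share, frontier estimate (years of life expectancy),
    node error R(t), and member country codes."""
    return _read("oecd36_terminal_nodes_reference.csv")
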