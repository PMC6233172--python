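"""Diversity-decline and disassembly plots (mean line + spread band)."""

from __future__ import annotations

import numpy as np

from .analysis import DisassemblyCurve
from .dynamics import DiversityCurve

_COLORS = {"tolerance": "#3465a4", "coextinction": "#c0399f"}


def plot_diversity_curves(curves: list[DiversityCurve], ax=None, band: str = "minmax"):
    """Mean surviving-fraction curve per scenario with a min–max (or none) band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    by_scenario: dict[str, list[DiversityCurve]] = {}
    for c in curves:
        by_scenario.setdefault(c.scenario, []).append(c)
    for scenario, group in by_scenario.items():
        x = group[0].step / group[0].step[-1]
        ys = np.vstack([c.surviving_fraction() for c in group])
        color = _COLORS.get(scenario, None)
        ax.plot(x, ys.mean(axis=0), label=scenario, color=color)
        if band == "minmax" and len(group) > 1:
            ax.fill_between(x, ys.min(axis=0), ys.max(axis=0), alpha=0.2, color=color)
    ax.set_xlabel("normalized environmental change")
    ax.set_ylabel("surviving diversity fraction")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax


def plot_disassembly(curves: list[DisassemblyCurve], ax=None, ci: float = 0.99):
    """Mean decline per removal order with a normal-approximation CI band."""
    import matplotlib.pyplot as plt
    from scipy import stats

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    by_order: dict[str, list[DisassemblyCurve]] = {}
    for c in curves:
        by_order.setdefault(c.order, []).append(c)
    grid = np.linspace(0, 1, 101)
    z = stats.norm.ppf(0.5 + ci / 2)
    for order, group in by_order.items():
        ys = np.vstack(
            [
                np.interp(grid, c.removed / max(c.initial_richness, 1), c.surviving_fraction)
                for c in group
            ]
        )
        mean = ys.mean(axis=0)
        ax.plot(grid, mean, label=order)
        if len(group) > 1:
            se = ys.std(axis=0, ddof=1) / np.sqrt(len(group))
            ax.fill_between(grid, mean - z * se, mean + z * se, alpha=0.2)
    ax.set_xlabel("fraction of species removed")
    ax.set_ylabel("surviving diversity fraction")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax
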