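"""Per-position diagnostic plots (artifacts, not tested surfaces).

Figures are rendered headlessly with the Agg canvas; numeric CSVs are the
authoritative outputs.
"""

from __future__ import annotations

import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from .energy import EnergyProfile
from .signals import SignalMatrix


def _save(fig: Figure, path) -> None:
    FigureCanvasAgg(fig)
    fig.savefig(path, dpi=120, bbox_inches="tight")


def plot_depth(depth_control, depth_modified, path, truth_positions=()) -> None:
    fig = Figure(figsize=(8, 3))
    ax = fig.add_subplot()
    ax.plot(depth_control.index, depth_control.to_numpy(), label="control")
    ax.plot(depth_modified.index, depth_modified.to_numpy(), label="modified")
    for p in truth_positions:
        ax.axvline(p, color="0.85", zorder=0)
    ax.set_xlabel("reference position")
    ax.set_ylabel("depth")
    ax.legend(frameon=False)
    _save(fig, path)


def plot_tv_delta(delta_df, path, truth_positions=()) -> None:
    fig = Figure(figsize=(8, 3))
    ax = fig.add_subplot()
    ax.bar(delta_df["position"], delta_df["delta_pct"], width=1.0)
    for p in truth_positions:
        ax.axvline(p, color="0.85", zorder=0)
    ax.set_xlabel("reference position")
    ax.set_ylabel("ΔTV (modified − control, %)")
    _save(fig, path)


def plot_energy_profile(profile: EnergyProfile, path, truth_positions=()) -> None:
    fig = Figure(figsize=(8, 3))
    ax = fig.add_subplot()
    v = profile.values()
    ax.plot(v.index, v.to_numpy())
    for p in truth_positions:
        ax.axvline(p, color="0.85", zorder=0)
    ax.set_xlabel("reference position")
    ax.set_ylabel("energy distance")
    _save(fig, path)


def plot_signal_bands(
    modified: SignalMatrix, control: SignalMatrix, channel: str, path,
    truth_positions=(),
) -> None:
    """Median ± IQR band of one signal channel for both samples."""
    fig = Figure(figsize=(8, 3))
    ax = fig.add_subplot()
    for sm, label in ((control, "control"), (modified, "modified")):
        g = sm.df.groupby("position")[channel]
        med = g.median()
        q1 = g.quantile(0.25)
        q3 = g.quantile(0.75)
        ax.plot(med.index, med.to_numpy(), label=label)
        ax.fill_between(med.index, q1.to_numpy(), q3.to_numpy(), alpha=0.3)
    for p in truth_positions:
        ax.axvline(p, color="0.85", zorder=0)
    ax.set_xlabel("reference position")
    ax.set_ylabel(channel)
    ax.legend(frameon=False)
    _save(fig, path)
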