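"""Diagnostic figures: bifurcation diagram, polar histograms, K-vs-Omega."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .kuramoto import equilibrium_curve  # noqa: E402
from .nonperiodic import phase_diff_histogram  # noqa: E402


def plot_bifurcation(ax=None, control=None):
    """Equilibrium Phi vs K/Omega; solid = stable, dashed = unstable."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    curve = equilibrium_curve(control)
    for stable, style in ((True, "k."), (False, "r.")):
        g = curve[curve["stable"] == stable]
        ax.plot(g["control"], g["phi"], style, markersize=2,
                label="stable" if stable else "unstable")
    ax.set_xlabel(r"$K/\Omega$")
    ax.set_ylabel(r"$\Phi$ (rad)")
    ax.axvline(-1, color="gray", lw=0.5)
    ax.axvline(1, color="gray", lw=0.5)
    ax.legend(loc="best", fontsize=8)
    return ax


def plot_phase_diff_polar(phi, n_bins: int = 18, ax=None):
    """Polar probability histogram of wrapped phase differences."""
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4, 4))
    edges, probs = phase_diff_histogram(phi, n_bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ax.bar(centers, probs, width=np.diff(edges), alpha=0.7, edgecolor="k")
    return ax


def plot_k_vs_omega(fit_table, ax=None):
    """Scatter of fitted K against fitted Omega, one color per group."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for gname, g in fit_table.groupby("group"):
        ax.scatter(g["Omega"], g["K"], s=8, alpha=0.6, label=gname)
    ax.set_xlabel(r"$\Omega$ (Hz)")
    ax.set_ylabel(r"$K$ (Hz)")
    ax.legend(loc="best", fontsize=8)
    return ax
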