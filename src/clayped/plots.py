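"""Matplotlib figures for the standard observables (PNG/SVG, Agg-safe)."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .adsorption_templating import OrientationHistogram, RDFResult
from .surface_dynamics import DiffusionStats
from .wetdry_kinetics import CycleLedger

__all__ = [
    "plot_adsorption_vs_hydration",
    "plot_rdf",
    "plot_orientation",
    "plot_direction_polar",
    "plot_cycle_distributions",
]


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_adsorption_vs_hydration(
    percent_by_hydration: Mapping[float, float], path: str | Path
) -> Path:
    """Percent adsorbed as a function of waters per amino acid."""
    w = sorted(percent_by_hydration)
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.plot(w, [percent_by_hydration[k] for k in w], "o-")
    ax.set_xlabel("hydration (W/AA)")
    ax.set_ylabel("% adsorbed")
    ax.set_ylim(0, 105)
    ax.invert_xaxis()  # dehydration reads left to right
    return _save(fig, path)


def plot_rdf(results: Sequence[RDFResult], path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    for res in results:
        ax.plot(res.r, res.g, label="-".join(res.pair))
    ax.axhline(1.0, color="0.7", lw=0.8)
    ax.set_xlabel("r (Å)")
    ax.set_ylabel("g(r)")
    ax.legend(fontsize=8)
    return _save(fig, path)


def plot_orientation(hist: OrientationHistogram, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.bar(hist.bin_centers, hist.counts, width=1.0)
    ax.set_xlabel("Θ (deg, 0 = ⊥ surface)")
    ax.set_ylabel("count")
    ax.set_xlim(0, 90)
    return _save(fig, path)


def plot_direction_polar(stats: DiffusionStats, path: str | Path) -> Path:
    """Polar histogram of diffusion directions."""
    fig = plt.figure(figsize=(3.8, 3.8))
    ax = fig.add_subplot(projection="polar")
    theta = np.deg2rad(np.arange(360) + 0.5)
    ax.bar(theta, stats.histogram, width=np.deg2rad(1.0))
    ax.set_yticklabels([])
    return _save(fig, path)


def plot_cycle_distributions(ledger: CycleLedger, path: str | Path, max_len: int = 16) -> Path:
    """Converged chain-length distributions per wetting-drying cycle."""
    fig, ax = plt.subplots(figsize=(5.0, 3.4))
    n_cycles = ledger.surface.shape[0]
    cmap = plt.get_cmap("viridis")
    lengths = np.arange(1, max_len + 1)
    for c in range(n_cycles):
        ax.plot(lengths, ledger.surface[c, :max_len], color=cmap(c / max(1, n_cycles - 1)),
                lw=1.0)
    ax.axhline(ledger.params.threshold, color="0.6", ls="--", lw=0.8)
    ax.set_yscale("log")
    ax.set_ylim(bottom=1e-3)
    ax.set_xlabel("chain length n")
    ax.set_ylabel("surface concentration")
    return _save(fig, path)
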