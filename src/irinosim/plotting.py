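"""Optional matplotlib views of simulation and study outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .compounds import COMPOUND_NAMES

__all__ = [
    "plot_profiles",
    "plot_concentration_by_genotype",
    "plot_reproduction_frequency",
    "plot_significance_heatmap",
]


def plot_profiles(profiles: pd.DataFrame, observed: pd.DataFrame | None = None, ax=None):
    """Semilog overlay of simulated (lines) and observed (dots) profiles."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    for comp in COMPOUND_NAMES:
        sub = profiles[profiles["compound"] == comp]
        ax.semilogy(sub["time_h"], sub["concentration_nM"], label=comp)
        if observed is not None:
            obs = observed[observed["compound"] == comp]
            ax.semilogy(obs["time_h"], obs["concentration_nM"], "o", ms=4)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("blood concentration (nM)")
    ax.legend(frameon=False)
    return ax


def plot_concentration_by_genotype(exposures: pd.DataFrame, locus: str, ax=None):
    """Box plot of dose-normalized SN-38 C90 per diplotype at one locus."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    groups = [
        exposures.loc[exposures[locus] == g, "c90_sn38_per_dose"].to_numpy()
        for g in ("wild", "het", "hom")
    ]
    labels = [f"{g}\n(n={len(v)})" for g, v in zip(("wild", "het", "hom"), groups)]
    ax.boxplot([v for v in groups if len(v)],
               tick_labels=[l for l, v in zip(labels, groups) if len(v)])
    ax.set_ylabel("SN-38 C90 / dose (nM/mg)")
    ax.set_title(locus)
    return ax


def plot_reproduction_frequency(sweep: pd.DataFrame, ax=None):
    """Reproduction frequency vs population size (log x-axis)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.semilogx(sweep["n"], sweep["freq_ugt1a1"], "x-", label="UGT1A1*28")
    ax.semilogx(sweep["n"], sweep["freq_slco1b1"], "o-", label="SLCO1B1 521")
    ax.axhline(0.8, color="gray", ls="--", lw=0.8)
    ax.set_xlabel("number of virtual patients")
    ax.set_ylabel("reproduction frequency")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    return ax


def plot_significance_heatmap(heatmap: pd.DataFrame, ax=None):
    """Associations x parameter-set significance-count map."""
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.4 * heatmap.shape[1], 6))
    im = ax.imshow(heatmap.to_numpy(), aspect="auto", cmap="YlGn")
    ax.set_xticks(np.arange(heatmap.shape[1]), labels=heatmap.columns)
    ax.set_yticks(np.arange(heatmap.shape[0]), labels=heatmap.index, fontsize=7)
    ax.figure.colorbar(im, ax=ax, label="significant replicates")
    return ax
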