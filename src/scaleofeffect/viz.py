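"""Diagnostic figures: R² profiles, effect-size dot-and-whisker, bootstrap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .scale_selection import BootstrapScaleDistribution, ScaleProfile

_COMPONENT_COLORS = {"forest": "#2a7e43", "urban": "#7d7d7d", "agriculture": "#d88c2a"}


def plot_scale_profile(profile: ScaleProfile, path: str | Path) -> None:
    """R² against buffer radius with the selected scale marked."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    color = _COMPONENT_COLORS.get(profile.component, "C0")
    ax.plot(profile.radii, profile.r2, color=color, lw=1.2)
    ax.axvline(profile.selected_scale, ls="--", color="k", lw=0.8)
    ax.set_xlabel("buffer radius (m)")
    ax.set_ylabel("R²")
    ax.set_title(f"{profile.response_kind} ~ {profile.component}", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_effect_sizes(effects: pd.DataFrame, path: str | Path) -> None:
    """Standardized coefficients ± SE, one panel per response."""
    kinds = list(dict.fromkeys(effects["response_kind"]))
    fig, axes = plt.subplots(
        len(kinds), 1, figsize=(5, 1.6 * len(kinds) + 1), squeeze=False
    )
    for ax, kind in zip(axes.ravel(), kinds):
        sub = effects[effects["response_kind"] == kind]
        ypos = np.arange(len(sub))
        ax.errorbar(
            sub["beta_std"], ypos, xerr=sub["se_std"], fmt="o",
            ecolor="gray", markerfacecolor="none",
        )
        ax.axvline(0, color="k", lw=0.6)
        ax.set_yticks(ypos)
        ax.set_yticklabels(
            [f"{c} ({s:.0f} m) {sig}" for c, s, sig in
             zip(sub["component"], sub["scale_used_m"], sub["signif"])]
        )
        ax.set_title(kind, fontsize=9)
    axes.ravel()[-1].set_xlabel("standardized coefficient ± SE")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_bootstrap_hist(dist: BootstrapScaleDistribution, path: str | Path) -> None:
    """Histogram of bootstrap selected scales with the full-data scale marked."""
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.hist(dist.scales, bins=30, color="#5a8fbb", edgecolor="white")
    ax.axvline(dist.full_data_scale, color="k", ls="--", lw=1)
    ax.set_xlabel("selected scale (m)")
    ax.set_ylabel("bootstrap replicates")
    ax.set_title(f"{dist.response_kind} ~ {dist.component} (B={dist.B})", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
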