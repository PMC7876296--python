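"""Static report figures: notched box panels, per-group density panels with
reference bands, and a correlation matrix with significance stars."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from carproc.nptests import ba_density_test, notch_interval  # noqa: E402
from carproc.pipeline import BATTERY_INDICATORS  # noqa: E402
from carproc.reference import BMI_GROUPS  # noqa: E402

GROUP_COLORS = {"NW": "black", "OW": "tab:blue", "OB": "tab:red"}


def notched_box_panels(indicator_table: pd.DataFrame, group_labels, path) -> None:
    """One notched box panel per indicator, groups ordered NW, OW, OB."""
    groups = np.asarray(group_labels)
    fig, axes = plt.subplots(2, 3, figsize=(12, 7), sharey=True)
    for ax, name in zip(axes.ravel(), BATTERY_INDICATORS):
        stats_list = []
        for g in BMI_GROUPS:
            vals = indicator_table.loc[groups == g, name].to_numpy()
            notch = notch_interval(vals)
            stats_list.append(
                {
                    "label": g,
                    "med": notch.median,
                    "q1": notch.q1,
                    "q3": notch.q3,
                    "cilo": notch.lower,
                    "cihi": notch.upper,
                    "whislo": float(vals.min()),
                    "whishi": float(vals.max()),
                    "fliers": [],
                }
            )
        ax.bxp(stats_list, shownotches=True)
        ax.set_title(name)
        ax.set_ylim(0, 100)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def density_panels(indicator_table: pd.DataFrame, group_labels, path,
                   nboot: int = 200, seed: int = 0) -> None:
    """Pairwise density comparisons with gray reference bands; p-values in
    red when at or below the Bonferroni-corrected level."""
    groups = np.asarray(group_labels)
    pairs = (("NW", "OW"), ("NW", "OB"), ("OW", "OB"))
    fig, axes = plt.subplots(
        len(BATTERY_INDICATORS), 3, figsize=(12, 3 * len(BATTERY_INDICATORS))
    )
    for i, name in enumerate(BATTERY_INDICATORS):
        for j, (ga, gb) in enumerate(pairs):
            ax = axes[i, j]
            a = indicator_table.loc[groups == ga, name].to_numpy()
            b = indicator_table.loc[groups == gb, name].to_numpy()
            comp = ba_density_test(a, b, nboot=nboot, seed=seed + i * 3 + j,
                                   groups_compared=f"{ga}-{gb}")
            ax.fill_between(comp.grid, comp.band_lower, comp.band_upper,
                            color="0.85", label="reference band")
            ax.plot(comp.grid, comp.density_g1, color=GROUP_COLORS[ga], label=ga)
            ax.plot(comp.grid, comp.density_g2, color=GROUP_COLORS[gb], label=gb)
            sig = comp.p_value <= 0.05 / 3
            ax.set_title(
                f"{name} {ga} vs {gb}  P = {comp.p_value:.3f}",
                color="red" if sig else "black",
                fontsize=9,
            )
            if i == 0 and j == 0:
                ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def correlation_plot(r: pd.DataFrame, codes: pd.DataFrame, path) -> None:
    """Heatmap of Pearson correlations annotated with significance stars."""
    fig, ax = plt.subplots(figsize=(10, 9))
    im = ax.imshow(r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(r.columns)), r.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(r.index)), r.index, fontsize=7)
    for i in range(len(r.index)):
        for j in range(len(r.columns)):
            if i == j:
                continue
            ax.text(
                j,
                i,
                f"{r.iat[i, j]:.2f}{codes.iat[i, j]}",
                ha="center",
                va="center",
                fontsize=5,
            )
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
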