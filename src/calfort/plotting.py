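"""Density plots of pre/post-fortification usual-intake distributions."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

from .reference_values import DRIEntry
from .usual_intake import UsualIntakeDistribution

__all__ = ["plot_pre_post_density", "save_density_plots"]


def _weighted_kde(dist: UsualIntakeDistribution):
    values = dist.values_mg
    if np.ptp(values) == 0:  # degenerate: all mass at one point
        return None
    return stats.gaussian_kde(values, weights=dist.weights)


def plot_pre_post_density(
    pre: UsualIntakeDistribution,
    post: UsualIntakeDistribution,
    entry: DRIEntry,
    label: str,
    ax=None,
):
    """Overlay the baseline and fortified usual-intake densities with the
    EAR and UL marked; returns the matplotlib axes."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    hi = max(pre.values_mg.max(), post.values_mg.max(), entry.ul_mg) * 1.1
    grid = np.linspace(0.0, hi, 400)
    for dist, name, color in ((pre, "baseline", "C0"), (post, "fortified", "C1")):
        kde = _weighted_kde(dist)
        if kde is None:
            ax.axvline(float(dist.values_mg[0]), color=color, label=name)
        else:
            ax.plot(grid, kde(grid), color=color, label=name)
    ax.axvline(entry.ear_mg, color="grey", linestyle="--", linewidth=1, label="EAR")
    ax.axvline(entry.ul_mg, color="grey", linestyle=":", linewidth=1, label="UL")
    ax.set_xlabel("usual calcium intake (mg/day)")
    ax.set_ylabel("density")
    ax.set_title(label)
    ax.legend(frameon=False, fontsize=8)
    return ax


def save_density_plots(results, outdir: str | Path) -> list[Path]:
    """One PNG per group; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for r in results.results:
        label = r.group.label
        fig, ax = plt.subplots(figsize=(6, 4))
        results.plot_density(label, ax=ax)
        safe = label.replace(" ", "").replace("<=", "le").replace(">=", "ge")
        path = outdir / f"{safe}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
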