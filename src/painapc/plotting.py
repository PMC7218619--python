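"""Fan charts for projected rates: observed points, predictive mean, nested bands."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .lexis import APCTable
from .projection import ProjectionResult

__all__ = ["plot_projection_fan"]


def plot_projection_fan(
    table: APCTable, results: Sequence[ProjectionResult], max_panels: int | None = None
):
    """One panel per age group: observed rates, projected mean line and shaded
    central credible bands (innermost band narrowest), with a dashed line where
    projection starts."""
    ages = [a.label for a in table.age_groups]
    if max_panels:
        ages = ages[:max_panels]
    ncol = min(4, len(ages))
    nrow = int(np.ceil(len(ages) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.4 * nrow), squeeze=False)
    obs_x = [p.start_year + (p.width - 1) / 2 for p in table.periods]
    proj_start = table.periods[-1].end_year + 0.5
    for ax_idx, age in enumerate(ages):
        ax = axes[ax_idx // ncol][ax_idx % ncol]
        i = ages.index(age)
        rates = np.where(table.n[i] > 0, table.y[i] / np.maximum(table.n[i], 1), np.nan)
        ax.plot(obs_x, rates, "o", color="black", ms=4, label="observed")
        cell = sorted(
            (r for r in results if r.age_label == age), key=lambda r: r.period.index
        )
        if cell:
            px = [r.period.start_year + (r.period.width - 1) / 2 for r in cell]
            levels = sorted(cell[0].bands, reverse=True)
            for li, lev in enumerate(levels):
                lo = [r.bands[lev][0] for r in cell]
                hi = [r.bands[lev][1] for r in cell]
                ax.fill_between(px, lo, hi, color="C0", alpha=0.18 + 0.1 * li, lw=0)
            ax.plot(px, [r.mean for r in cell], "-", color="C0", label="projected mean")
        ax.axvline(proj_start, ls="--", color="grey", lw=1)
        ax.set_title(age, fontsize=9)
        ax.set_ylim(0, 1)
    for k in range(len(ages), nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    fig.suptitle(f"Projected rates, stratum {table.stratum}")
    fig.tight_layout()
    return fig
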