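"""Optional figures: volcano plot of the combined statistics, the
tumors x stages similarity heatmap, and median-split Kaplan-Meier
curves.  Each function returns the matplotlib Figure."""

from __future__ import annotations

import numpy as np
import matplotlib.pyplot as plt


def volcano(combined, fdr_threshold: float = 0.05, ax=None):
    """Combined z vs -log10 joint p, signature features highlighted."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    t = combined.table
    sel = t["selected"]
    ax.scatter(t.loc[~sel, "z_combined"], -np.log10(t.loc[~sel, "p_joint"]),
               s=8, c="grey", alpha=0.6, label="not selected")
    ax.scatter(t.loc[sel, "z_combined"], -np.log10(t.loc[sel, "p_joint"]),
               s=10, c="crimson", label="signature")
    ax.set_xlabel("combined z (poor vs good prognosis)")
    ax.set_ylabel("-log10 joint p")
    ax.legend(frameon=False, fontsize=8)
    return ax.figure


def stage_heatmap(tumor_correlations, ax=None):
    """Heatmap of per-tumor similarity to each differentiation stage."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 6))
    rho = tumor_correlations.rho
    order = rho["OP1"].sort_values().index
    im = ax.imshow(rho.loc[order].to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-1, vmax=1, interpolation="nearest")
    ax.set_xticks(range(rho.shape[1]), rho.columns, rotation=45)
    ax.set_yticks([])
    ax.set_ylabel(f"{rho.shape[0]} tumors (sorted by OP1 similarity)")
    ax.figure.colorbar(im, ax=ax, label="Spearman rho")
    return ax.figure


def km_plot(km_result, ax=None):
    """Step curves for the above/below-median similarity groups."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for name, curve in km_result.curves.items():
        ax.step(curve["time"], curve["survival"], where="post", label=name)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False, title=f"log-rank p = {km_result.logrank_p:.2g}")
    return ax.figure
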