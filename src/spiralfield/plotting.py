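"""Quick-look plots of simulated session results."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import CellTable


def plot_cell_means(table: CellTable, x: str, hue: str | None = "group",
                    dv: str = "p_correct", ax=None):
    """Group mean accuracy (+/- 1 SEM across subjects) against a factor.

    Returns the matplotlib axes; lazy-imports matplotlib so headless
    batch runs never touch a display backend.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    data = table.data
    hue_vals = [None] if hue is None else list(pd.unique(data[hue]))
    for hv in hue_vals:
        sub = data if hv is None else data[data[hue] == hv]
        per_subj = sub.groupby(["subject", x], observed=True)[dv].mean().reset_index()
        agg = per_subj.groupby(x, observed=True)[dv]
        mean = agg.mean()
        sem = agg.std(ddof=1) / np.sqrt(agg.size())
        ax.errorbar(mean.index, mean.to_numpy(), yerr=sem.to_numpy(),
                    marker="o", capsize=3, label=None if hv is None else str(hv))
    ax.set_xlabel(x)
    ax.set_ylabel("proportion correct")
    ax.set_ylim(0.0, 1.02)
    ax.axhline(0.25, color="gray", lw=0.8, ls=":")
    if hue is not None:
        ax.legend(title=hue)
    return ax
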