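"""Bar-chart rendering of per-condition score distributions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .design import SCORE_LEVELS


def plot_score_distribution(table, ax=None):
    """Grouped bars of favourable vs unfavourable score percentages.

    ``table`` is the output of
    :func:`vgrlab.reliability.score_distribution_table`: one group of five
    bars (scores -2..+2) per image condition.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(1.6 * len(table) + 2, 4))
    n_cond = len(table)
    width = 0.16
    offsets = (np.arange(len(SCORE_LEVELS)) - 2) * width
    x = np.arange(n_cond)
    cmap = plt.get_cmap("RdBu")
    for k, s in enumerate(SCORE_LEVELS):
        ax.bar(
            x + offsets[k],
            table[f"score_{s:+d}_pct"],
            width=width,
            label=f"score {s:+d}",
            color=cmap(0.1 + 0.2 * k),
            edgecolor="black",
            linewidth=0.3,
        )
    labels = [
        f"{r.tube_load:g} mAs\n{r.algorithm}" for r in table.itertuples()
    ]
    ax.set_xticks(x)
    ax.set_xticklabels(labels)
    ax.set_ylabel("share of assessments (%)")
    ax.legend(fontsize=8, ncol=5, loc="upper center")
    ax.set_ylim(0, max(100.0, ax.get_ylim()[1]))
    return ax
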