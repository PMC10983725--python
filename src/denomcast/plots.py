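"""Basic observed-vs-predicted scatter plots for the prediction chains."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_observed_vs_predicted"]


def plot_observed_vs_predicted(observed: pd.DataFrame, predicted: pd.DataFrame,
                               value_col: str, out_path, title: str = ""):
    """Scatter of a quantity over month, observed rows as circles and
    predicted rows as diamonds, coloured by centre type (REC black, REG blue).

    ``observed`` needs ``month_index``, ``centre_type`` and ``value_col``;
    ``predicted`` needs ``month_index``, ``centre_type`` and ``point``.
    Returns the matplotlib figure (also saved to ``out_path`` when given).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4.5))
    colours = {"REC": "black", "REG": "tab:blue"}
    for ctype, colour in colours.items():
        obs = observed[observed["centre_type"] == ctype]
        ax.scatter(obs["month_index"], obs[value_col], s=18, marker="o",
                   facecolors="none", edgecolors=colour,
                   label=f"observed ({ctype})")
        pred = predicted[predicted["centre_type"] == ctype]
        ax.scatter(pred["month_index"], pred["point"], s=20, marker="D",
                   color=colour, alpha=0.6, label=f"predicted ({ctype})")
    ax.set_xlabel("month index")
    ax.set_ylabel(value_col)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8, ncol=2)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
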