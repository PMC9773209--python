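"""Optional plotting helpers (requires matplotlib)."""

from __future__ import annotations

import numpy as np
import pandas as pd


def condition_boxplot(table: pd.DataFrame, conditions, ax=None):
    """Box plot of percent correct per sentence condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    data = [table[c].dropna().to_numpy() for c in conditions]
    ax.boxplot(data, tick_labels=[c.replace("_", "\n") for c in conditions])
    ax.set_ylabel("keywords correct (%)")
    ax.set_ylim(0, 100)
    return ax


def ability_scatter(table: pd.DataFrame, predictor: str, condition: str, ax=None):
    """Scatter of one condition score against one ability measure."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    sub = table[[predictor, condition]].dropna()
    ax.scatter(sub[predictor], sub[condition], s=12, alpha=0.7)
    coef = np.polyfit(sub[predictor], sub[condition], 1)
    xs = np.linspace(sub[predictor].min(), sub[predictor].max(), 50)
    ax.plot(xs, np.polyval(coef, xs), color="k", lw=1)
    ax.set_xlabel(predictor)
    ax.set_ylabel(condition)
    return ax
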