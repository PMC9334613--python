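"""Report figures: coherence by condition/pairing and coherence-over-period."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

_CONDITION_ORDER = ["FreePlay", "PredictionDifferent", "PredictionSame", "Control", "Rest"]


def coherence_boxplot(table: pd.DataFrame, by: str = "pairing", ax=None):
    """Box plots of WTC values per condition, split by pairing (or region)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    conds = [c for c in _CONDITION_ORDER if c in set(table["condition"])]
    groups = sorted(table[by].unique())
    width = 0.8 / len(groups)
    for gi, g in enumerate(groups):
        data = [
            table.loc[(table["condition"] == c) & (table[by] == g), "wtc_value"].values
            for c in conds
        ]
        pos = [i + (gi - (len(groups) - 1) / 2) * width for i in range(len(conds))]
        bp = ax.boxplot(data, positions=pos, widths=width * 0.9, patch_artist=True)
        color = plt.get_cmap("tab10")(gi)
        for patch in bp["boxes"]:
            patch.set_facecolor(color)
            patch.set_alpha(0.6)
        ax.plot([], [], color=color, label=str(g))
    ax.set_xticks(range(len(conds)))
    ax.set_xticklabels(conds, rotation=20)
    ax.set_ylabel("wavelet coherence")
    ax.legend(title=by)
    return ax


def coherence_period_plot(curve: pd.DataFrame, ax=None):
    """Grand-average coherence vs. Fourier period, one line per condition."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for cond, sub in curve.groupby("condition"):
        sub = sub.sort_values("period_s")
        ax.plot(sub["period_s"], sub["coherence"], label=cond)
    ax.set_xlabel("Fourier period (s)")
    ax.set_ylabel("coherence grand average")
    ax.set_xscale("log")
    ax.legend()
    return ax
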