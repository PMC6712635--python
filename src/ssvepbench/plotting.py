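"""Single plotting helper: macro F-score versus analysis-window length."""

from __future__ import annotations

import pandas as pd


def plot_f_vs_window(results: pd.DataFrame, ax=None, montage: str | None = None):
    """Line chart of macro_f against window_s, one line per decoder.

    ``results`` is the long-format sweep table (montage, decoder, window_s,
    macro_f).  Returns the matplotlib Axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if montage is not None:
        results = results[results["montage"] == montage]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for name, grp in results.groupby("decoder"):
        grp = grp.sort_values("window_s")
        ax.plot(grp["window_s"], grp["macro_f"], marker="o", label=name)
    ax.set_xlabel("time window (s)")
    ax.set_ylabel("macro F-score")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=8)
    ax.grid(alpha=0.3)
    return ax
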