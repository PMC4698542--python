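"""Optional bar-chart convenience mirroring the study's figure style."""

from __future__ import annotations

import pandas as pd


def plot_group_bars(
    summaries: pd.DataFrame,
    measure: str,
    matrix: pd.DataFrame | None = None,
    reference: str = "normal",
    ax=None,
):
    """Bar chart of group means ± SEM for one measure, starred vs *reference*.

    Stars come from the comparison matrix rows with the given reference
    group; returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    sub = summaries.loc[summaries["measure"] == measure]
    if sub.empty:
        raise ValueError(f"measure {measure!r} not found in summaries")
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    groups = list(sub["group"])
    ax.bar(groups, sub["mean"], yerr=sub["sem"], capsize=3, color="0.6", edgecolor="0.2")
    ax.axhline(1.0 if sub["mean"].abs().max() > 0.5 else 0.0, lw=0.5, color="0.3")
    ax.set_ylabel("fold of reference" if (sub["mean"] > 0).all() else "contrast index")
    ax.set_title(measure)
    if matrix is not None:
        stars = matrix.loc[
            (matrix["measure"] == measure) & (matrix["reference"] == reference)
        ].set_index("comparator")["stars"]
        top = (sub["mean"] + sub["sem"]).max()
        for i, g in enumerate(groups):
            mark = stars.get(g, "")
            if mark and g != reference:
                ax.text(i, top * 1.03, mark, ha="center", fontsize=9)
    ax.tick_params(axis="x", rotation=30)
    return ax
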