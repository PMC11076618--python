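"""Figure panels following the cohort-report conventions.

Boxes span Q1–Q3, the horizontal line is the median, the white dot the
mean, whiskers end at Q1/Q3 ∓/± 1.5·IQR and black dots beyond them are
outliers.  Contrast annotations use the significance-star convention
(* q <= 0.1, ** q < 0.01, *** q < 0.001, **** q < 0.0001).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from fibremorph.stats import boxplot_summary


def metric_boxplot(
    table: pd.DataFrame,
    metric: str,
    by: str = "condition",
    ax=None,
    log_scale: bool = False,
):
    """Boxplot of a per-image metric by condition.

    Ratio metrics such as the FTR are conventionally drawn with a
    logarithmic y-axis (``log_scale=True``).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * table[by].nunique() + 1, 4))
    groups = sorted(table[by].unique())
    for pos, name in enumerate(groups, start=1):
        values = table.loc[table[by] == name, metric].dropna().to_numpy()
        if values.size == 0:
            continue
        s = boxplot_summary(values)
        inliers = values[(values >= s.whisker_lo) & (values <= s.whisker_hi)]
        lo, hi = (inliers.min(), inliers.max()) if inliers.size else (s.q1, s.q3)
        ax.add_patch(plt.Rectangle((pos - 0.3, s.q1), 0.6, s.q3 - s.q1,
                                   fill=True, facecolor="#d8d8d8", edgecolor="black"))
        ax.hlines(s.median, pos - 0.3, pos + 0.3, color="black", lw=1.5)
        ax.vlines(pos, lo, s.q1, color="black", lw=1)
        ax.vlines(pos, s.q3, hi, color="black", lw=1)
        ax.plot(pos, s.mean, "o", mfc="white", mec="black", ms=6, zorder=3)
        if s.outliers.size:
            ax.plot(np.full(s.outliers.size, pos), s.outliers, "k.", ms=4)
    ax.set_xticks(range(1, len(groups) + 1), groups, rotation=45, ha="right")
    ax.set_ylabel(metric)
    if log_scale:
        ax.set_yscale("log")
    return ax
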