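"""Bar-chart rendering of per-visit metric summaries.

One grouped bar chart per metric: visits on the x-axis, one bar per
location, error bars from the standard errors, significance stars from
the baseline comparisons drawn above the bars.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .cohort import LOCATIONS, VISITS

__all__ = ["plot_visit_means"]


def plot_visit_means(
    aggregates: pd.DataFrame,
    path,
    comparisons: pd.DataFrame | None = None,
    metric_label: str | None = None,
) -> None:
    """Render per-(visit, location) means with SE bars to an image file.

    Parameters
    ----------
    aggregates
        Output of :func:`endooct.aggregate` for one metric.
    path
        Output image path (format from the extension, e.g. ``.png``).
    comparisons
        Optional output of :func:`endooct.compare_to_baseline`; star
        annotations are placed above the bars of later visits.
    metric_label
        Axis label; defaults to the metric name in the table.
    """
    metric = aggregates["metric"].iloc[0]
    label = metric_label or metric
    cells = aggregates[aggregates.location != "all"]

    fig, ax = plt.subplots(figsize=(7, 4))
    width = 0.2
    for i, loc in enumerate(LOCATIONS):
        sub = cells[cells.location == loc].set_index("visit")
        xs = [v + (i - 1.5) * width for v in VISITS if v in sub.index]
        means = [sub.loc[v, "mean"] for v in VISITS if v in sub.index]
        errs = [sub.loc[v, "se"] for v in VISITS if v in sub.index]
        bars = ax.bar(xs, means, width=width, yerr=errs, capsize=2, label=loc)
        if comparisons is not None:
            stars = comparisons[(comparisons.location == loc)
                                & (comparisons.metric == metric)]
            for bar, v in zip(bars, [v for v in VISITS if v in sub.index]):
                row = stars[stars.visit == v]
                if not row.empty and row.iloc[0].stars != "ns":
                    ax.text(bar.get_x() + bar.get_width() / 2,
                            bar.get_height() * 1.02,
                            row.iloc[0].stars, ha="center", fontsize=8)
    ax.set_xticks(list(VISITS))
    ax.set_xlabel("visit")
    ax.set_ylabel(label)
    ax.legend(title="location", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
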