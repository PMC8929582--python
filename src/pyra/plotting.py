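"""Population-trend plot: the windowed ratio curve with its uncertainty.

The plot is a view of numbers that are always also written to CSV/JSON —
it is never the only record of a result.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

from .estimator import SummaryTrend, TrendSeries

__all__ = ["plot_trend"]


def plot_trend(
    trend: TrendSeries,
    summary: SummaryTrend | None = None,
    path=None,
    title: str | None = None,
):
    """Plot the ratio curve, CI band, summary line and the no-trend baseline.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    fig, ax = plt.subplots(figsize=(8, 4.5))
    t = trend.times_in_cycles
    ax.axhline(1.0, color="green", lw=1.2, label="no trend (ratio = 1)")
    if trend.ci_low is not None and trend.ci_high is not None:
        ax.fill_between(
            t, trend.ci_low, trend.ci_high, color="C0", alpha=0.25,
            label=f"{100 * 0.95:.0f}% percentile band",
        )
    ax.plot(t, trend.ratios, color="black", lw=1.3, label="windowed ratio")
    if summary is not None:
        ax.axhline(summary.P_T, color="black", ls="--", lw=1.0,
                   label=f"summary ratio = {summary.P_T:.3f}")
        if summary.ci_low is not None and summary.ci_high is not None:
            ax.axhline(summary.ci_low, color="C0", ls="--", lw=0.8)
            ax.axhline(summary.ci_high, color="C0", ls="--", lw=0.8)
    ax.set_xlabel(f"time ({trend.cycle_config.unit}s, in cycles)")
    ax.set_ylabel("year-on-year ratio")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
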