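"""Moving-block bootstrap percentile confidence intervals.

Detection series are serially correlated at short range (weather, prey
movements, social behaviour), so i.i.d. resampling of pairs would understate
uncertainty.  The moving block bootstrap resamples *consecutive runs* of
``w`` pairs instead: with ``K`` pairs there are ``K − w + 1`` overlapping
blocks; a resample draws ``ceil(K / w)`` of them uniformly with replacement,
concatenates them in draw order and truncates to length ``K``.  The (y1, y2)
tuples are kept intact within blocks — resampling the two years
independently would destroy the pairing the method depends on.

``w`` should exceed the correlation scale of the data; 21 days is a
reasonable default for daily paired data and 3 for monthly.  Percentile
intervals are the empirical α/2 and 1−α/2 quantiles of the resampled
statistics; resamples whose statistic is undefined (zero denominator) are
dropped and counted.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

from .estimator import EstimatorConfig, SummaryTrend, TrendSeries, pyra_series, pyra_summary
from .pairing import PairedSeries

__all__ = [
    "BootstrapConfig",
    "BootstrapResult",
    "block_resample",
    "bootstrap_ci",
    "bootstrap_summary_ci",
    "summary_with_ci",
    "bootstrap_trend_bands",
]


@dataclasses.dataclass(frozen=True)
class BootstrapConfig:
    """Block span ``w``, resample count ``B``, significance ``alpha``, seed."""

    w: int = 21
    B: int = 1000
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.w < 2:
            raise ValueError("block span w must be >= 2")
        if self.B < 1:
            raise ValueError("number of resamples B must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


@dataclasses.dataclass
class BootstrapResult:
    """Percentile interval plus diagnostics."""

    low: float
    high: float
    point: float
    B: int
    n_undefined: int
    alpha: float
    w: int


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _resample_indices(
    K: int, w: int, n_resamples: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_resamples, K) pair indices built from overlapping blocks."""
    if K < w:
        raise ValueError(f"need at least w={w} pairs to block-resample, have K={K}")
    n_blocks = -(-K // w)  # ceil
    starts = rng.integers(0, K - w + 1, size=(n_resamples, n_blocks))
    idx = (starts[:, :, None] + np.arange(w)[None, None, :]).reshape(n_resamples, -1)
    return idx[:, :K]


def block_resample(
    paired: PairedSeries, w: int, rng: np.random.Generator | int | None = None
) -> PairedSeries:
    """One moving-block resample of a paired series, length K, pairs intact."""
    rng = _as_rng(rng)
    idx = _resample_indices(paired.K, w, 1, rng)[0]
    return paired.take(idx)


def bootstrap_summary_ci(
    paired: PairedSeries, config: BootstrapConfig | None = None
) -> BootstrapResult:
    """Percentile CI for the summary ratio P̂_T (vectorised fast path).

    Each resample statistic is ``Σ y2 / Σ y1`` over the resampled pairs;
    sums over blocks make this a pure gather-and-reduce, so all B resamples
    are evaluated in one shot.
    """
    cfg = config or BootstrapConfig()
    point = pyra_summary(paired).P_T
    rng = _as_rng(cfg.seed)
    idx = _resample_indices(paired.K, cfg.w, cfg.B, rng)
    s1 = paired.y1[idx].sum(axis=1)
    s2 = paired.y2[idx].sum(axis=1)
    good = s1 > 0
    if not good.any():
        raise ValueError("all bootstrap resamples have zero year-1 sums")
    stats = s2[good] / s1[good]
    low, high = np.quantile(stats, [cfg.alpha / 2, 1 - cfg.alpha / 2])
    return BootstrapResult(
        low=float(low),
        high=float(high),
        point=float(point),
        B=cfg.B,
        n_undefined=int((~good).sum()),
        alpha=cfg.alpha,
        w=cfg.w,
    )


def bootstrap_ci(
    paired: PairedSeries,
    statistic: Callable[[PairedSeries], float],
    config: BootstrapConfig | None = None,
) -> BootstrapResult:
    """Percentile CI for an arbitrary statistic of a paired series.

    The statistic is called on each resample; resamples where it raises
    ``ValueError`` or ``ZeroDivisionError`` or returns NaN are dropped and
    counted in ``n_undefined``.
    """
    cfg = config or BootstrapConfig()
    point = float(statistic(paired))
    rng = _as_rng(cfg.seed)
    stats = []
    n_undefined = 0
    for _ in range(cfg.B):
        resample = block_resample(paired, cfg.w, rng)
        try:
            val = float(statistic(resample))
        except (ValueError, ZeroDivisionError):
            n_undefined += 1
            continue
        if np.isnan(val):
            n_undefined += 1
            continue
        stats.append(val)
    if not stats:
        raise ValueError("statistic undefined on every bootstrap resample")
    low, high = np.quantile(stats, [cfg.alpha / 2, 1 - cfg.alpha / 2])
    return BootstrapResult(
        low=float(low),
        high=float(high),
        point=point,
        B=cfg.B,
        n_undefined=n_undefined,
        alpha=cfg.alpha,
        w=cfg.w,
    )


def summary_with_ci(
    paired: PairedSeries, config: BootstrapConfig | None = None
) -> SummaryTrend:
    """The summary trend with its percentile CI attached."""
    result = bootstrap_summary_ci(paired, config)
    summary = pyra_summary(paired)
    summary.ci_low = result.low
    summary.ci_high = result.high
    summary.n_boot_undefined = result.n_undefined
    return summary


def bootstrap_trend_bands(
    paired: PairedSeries,
    est_config: EstimatorConfig | None = None,
    boot_config: BootstrapConfig | None = None,
) -> TrendSeries:
    """The windowed trend series with per-point percentile bands.

    For each window of the trend series, resampling is restricted to blocks
    drawn from that window's own pairs (the statistic is local, so blocks
    from elsewhere in the series carry no information about it).  Windows
    holding fewer than ``max(w, min_pairs_per_window)`` pairs keep a NaN
    band.
    """
    ecfg = est_config or EstimatorConfig()
    bcfg = boot_config or BootstrapConfig()
    trend = pyra_series(paired, ecfg)
    C = paired.C
    I = C if ecfg.I is None else ecfg.I

    order = np.argsort(paired.k, kind="stable")
    ks = paired.k[order]
    y1 = paired.y1[order]
    y2 = paired.y2[order]
    starts = (trend.times - C // 2).astype(np.int64)
    lo = np.searchsorted(ks, starts, side="left")
    hi = np.searchsorted(ks, starts + I, side="left")

    rng = _as_rng(bcfg.seed)
    ci_low = np.full(len(starts), np.nan)
    ci_high = np.full(len(starts), np.nan)
    for i in range(len(starts)):
        m = int(hi[i] - lo[i])
        if not np.isfinite(trend.ratios[i]) or m < bcfg.w:
            continue
        idx = _resample_indices(m, bcfg.w, bcfg.B, rng) + lo[i]
        s1 = y1[idx].sum(axis=1)
        s2 = y2[idx].sum(axis=1)
        good = s1 > 0
        if not good.any():
            continue
        stats = s2[good] / s1[good]
        ci_low[i], ci_high[i] = np.quantile(stats, [bcfg.alpha / 2, 1 - bcfg.alpha / 2])
    trend.ci_low = ci_low
    trend.ci_high = ci_high
    return trend
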