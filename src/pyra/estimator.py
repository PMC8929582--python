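"""The paired-year ratio estimator family.

Let ``(y*_k, y*_{k+C})`` be the paired values at day position ``k`` and the
same position one cycle later.  The smoothed ratio with window span ``I`` is

    P̂_I(t*_k) = m_I(y*_{k+C}) / m_I(y*_k)

with ``m_I`` a forward moving average over ``[k, k+I)``.  Because numerator
and denominator windows contain the same day positions by construction, the
ratio of means equals the ratio of *sums* over the identical pair set, which
is what is computed here — this avoids divide-by-count asymmetry when pairs
are missing.  Three members of the family matter in practice:

* ``I = 0`` — the raw point ratio ``y*_{k+C} / y*_k`` (unstable near zero
  counts, undefined when the denominator year recorded zero);
* ``I = C`` — the trend series: the two-year window slides one unit at a
  time and each ratio is reported at the window midpoint ``k + C/2``;
* ``I = T`` (all pairs) — the summary statistic
  ``P̂_T = Σ y*_{k+C} / Σ y*_k``, with 1 the no-trend baseline and
  ``100 × (1 − P̂_T)`` the percent change over the monitored span.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .data_model import CycleConfig
from .pairing import PairedObservation, PairedSeries

__all__ = [
    "EstimatorConfig",
    "TrendSeries",
    "SummaryTrend",
    "forward_moving_mean",
    "pyra_point",
    "pyra_series",
    "pyra_summary",
    "pyra_summary_windowed",
]


@dataclasses.dataclass(frozen=True)
class EstimatorConfig:
    """Tuning knobs for the windowed ratio estimator.

    I:
        Smoother window span in time units; ``None`` means "use the cycle
        length C", the natural choice for multi-year data.
    min_pairs_per_window:
        Windows holding fewer pairs than this produce a missing value
        rather than an unstable ratio.  Default 30 (~8% of an annual
        window).
    zero_denominator_policy:
        "missing" (default) marks windows whose year-1 sum is zero as
        undefined; "epsilon" computes ``(num + ε) / (den + ε)`` instead,
        the additive adjustment familiar from log(1+x) transforms.
    """

    I: int | None = None
    min_pairs_per_window: int = 30
    zero_denominator_policy: str = "missing"
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if self.I is not None and self.I < 0:
            raise ValueError("window span I must be >= 0")
        if self.min_pairs_per_window < 1:
            raise ValueError("min_pairs_per_window must be >= 1")
        if self.zero_denominator_policy not in ("missing", "epsilon"):
            raise ValueError(
                f"unknown zero_denominator_policy {self.zero_denominator_policy!r}"
            )
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclasses.dataclass
class TrendSeries:
    """The midpoint-shifted sequence of windowed ratios with optional bands.

    ``times`` are day positions already shifted right by floor(C/2) so that
    each ratio sits midway between the two years it compares;
    ``times_in_cycles`` reports the same axis in fractional cycles.
    Missing ratios are NaN.
    """

    times: np.ndarray
    ratios: np.ndarray
    n_pairs: np.ndarray
    cycle_config: CycleConfig
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.ratios) == len(self.n_pairs) == n):
            raise ValueError("times, ratios, n_pairs must have equal length")
        for band in (self.ci_low, self.ci_high):
            if band is not None and len(band) != n:
                raise ValueError("confidence band length mismatch")

    @property
    def times_in_cycles(self) -> np.ndarray:
        return self.times / self.cycle_config.C

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.ratios)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "time": self.times,
                "time_cycles": self.times_in_cycles,
                "ratio": self.ratios,
                "n_pairs": self.n_pairs,
            }
        )
        frame["ci_low"] = np.nan if self.ci_low is None else self.ci_low
        frame["ci_high"] = np.nan if self.ci_high is None else self.ci_high
        return frame

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclasses.dataclass
class SummaryTrend:
    """The scalar summary ratio P̂_T and its interpretation.

    ``percent_change_over_span`` follows the whole-span reading
    ``100 × (1 − P_T)``; ``percent_change_per_cycle`` divides that by the
    span T in cycles for an average year-on-year reading.  Both are reported
    because both conventions appear in field use.
    """

    P_T: float
    K: int
    T: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot_undefined: int = 0

    @property
    def percent_change_over_span(self) -> float:
        return 100.0 * (1.0 - self.P_T)

    @property
    def percent_change_per_cycle(self) -> float:
        return self.percent_change_over_span / self.T

    def to_dict(self) -> dict:
        return {
            "P_T": self.P_T,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "K": self.K,
            "T": self.T,
            "percent_change_over_span": self.percent_change_over_span,
            "percent_change_per_cycle": self.percent_change_per_cycle,
            "n_boot_undefined": self.n_boot_undefined,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


# ------------------------------------------------------------------ smoother


def forward_moving_mean(
    positions: np.ndarray,
    values: np.ndarray,
    I: int,
    min_pairs: int = 1,
) -> np.ndarray:
    """Forward moving average: output at position p is the mean of the
    available values with positions in ``[p, p+I)``.

    Positions must be strictly increasing; windows holding fewer than
    ``min_pairs`` values yield NaN.  ``I`` must be >= 1 (the raw point
    values need no smoother).
    """
    if I < 1:
        raise ValueError("window span I must be >= 1; use pyra_point for I = 0")
    positions = np.asarray(positions)
    values = np.asarray(values, dtype=float)
    if len(positions) != len(values):
        raise ValueError("positions and values must have equal length")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    csum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.arange(len(positions))
    hi = np.searchsorted(positions, positions + I, side="left")
    n = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (csum[hi] - csum[lo]) / n
    out[n < min_pairs] = np.nan
    return out


# ---------------------------------------------------------------- estimators


def pyra_point(
    pair: PairedObservation | float,
    y2: float | None = None,
    zero_denominator_policy: str = "missing",
    epsilon: float = 1.0,
) -> float:
    """The raw point ratio y2/y1 for one pair; NaN when undefined.

    Accepts either a :class:`PairedObservation` or the two values
    ``pyra_point(y1, y2)``.
    """
    if isinstance(pair, PairedObservation):
        y1, y2v = pair.y1, pair.y2
    else:
        if y2 is None:
            raise TypeError("pyra_point needs a PairedObservation or (y1, y2)")
        y1, y2v = float(pair), float(y2)
    if y1 == 0.0:
        if zero_denominator_policy == "epsilon":
            return (y2v + epsilon) / (y1 + epsilon)
        return float("nan")
    return y2v / y1


def _sorted_arrays(paired: PairedSeries) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    order = np.argsort(paired.k, kind="stable")
    return paired.k[order], paired.y1[order], paired.y2[order]


def _window_sums(
    ks: np.ndarray, y1: np.ndarray, y2: np.ndarray, starts: np.ndarray, I: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c1 = np.concatenate([[0.0], np.cumsum(y1)])
    c2 = np.concatenate([[0.0], np.cumsum(y2)])
    lo = np.searchsorted(ks, starts, side="left")
    hi = np.searchsorted(ks, starts + I, side="left")
    return c1[hi] - c1[lo], c2[hi] - c2[lo], hi - lo


def pyra_series(
    paired: PairedSeries, config: EstimatorConfig | None = None
) -> TrendSeries:
    """The windowed ratio series: one ratio per window start position.

    The two-year window of span ``I`` (default C) advances one time unit at
    a time over the positions spanned by the pairs; the ratio for the window
    starting at ``k`` is ``Σ y2 / Σ y1`` over pairs with position in
    ``[k, k+I)``, reported at time ``k + floor(C/2)``.  Windows that hold
    fewer than ``min_pairs_per_window`` pairs — or whose denominator sum is
    zero under the "missing" policy — are NaN.
    """
    cfg = config or EstimatorConfig()
    if paired.K == 0:
        raise ValueError("cannot compute a trend series from an empty PairedSeries")
    C = paired.C
    I = C if cfg.I is None else cfg.I
    if I < 1:
        raise ValueError("pyra_series needs window span I >= 1")
    ks, y1, y2 = _sorted_arrays(paired)
    k_min, k_max = int(ks[0]), int(ks[-1])
    last_start = max(k_min, k_max - I + 1)
    starts = np.arange(k_min, last_start + 1)
    s1, s2, n = _window_sums(ks, y1, y2, starts, I)

    with np.errstate(invalid="ignore", divide="ignore"):
        if cfg.zero_denominator_policy == "epsilon":
            ratios = np.where(s1 > 0, s2 / np.where(s1 > 0, s1, 1.0),
                              (s2 + cfg.epsilon) / (s1 + cfg.epsilon))
        else:
            ratios = np.where(s1 > 0, s2 / np.where(s1 > 0, s1, 1.0), np.nan)
    ratios = np.where(n >= cfg.min_pairs_per_window, ratios, np.nan)
    times = (starts + C // 2).astype(float)
    return TrendSeries(times, ratios, n, paired.cycle_config)


def _span_in_cycles(paired: PairedSeries) -> int:
    C = paired.C
    first_day = int(paired.k.min())
    last_day = int(paired.k.max()) + C  # the year-2 member of the last pair
    return (last_day - 1) // C - (first_day - 1) // C + 1


def pyra_summary(paired: PairedSeries) -> SummaryTrend:
    """The summary trend statistic P̂_T = Σ y2 / Σ y1 over all pairs.

    All cycle pairs and all pooled sites contribute to the two sums.  T is
    the number of cycles spanned by the underlying days (4 for four years
    of data).  Raises when the series is empty or no year-1 detections were
    recorded.
    """
    if paired.K == 0:
        raise ValueError("cannot summarise an empty PairedSeries")
    denom = float(paired.y1.sum())
    if denom == 0.0:
        raise ValueError("summary undefined: no year-1 detections")
    return SummaryTrend(
        P_T=float(paired.y2.sum()) / denom,
        K=paired.K,
        T=float(_span_in_cycles(paired)),
    )


def pyra_summary_windowed(paired: PairedSeries, I: int) -> float:
    """Mean of the windowed ratios over pair-sequence windows of length I.

    Windows run over the pair sequence in time order: for
    ``j = 1 .. K − I + 1`` the j-th ratio is ``Σ y2 / Σ y1`` over pairs
    ``j .. j+I−1``; the statistic is their mean.  With ``I = K`` this
    reduces to the summary statistic P̂_T.  Windows with a zero denominator
    are dropped from the mean.
    """
    K = paired.K
    if not (1 <= I <= K):
        raise ValueError(f"window span I must lie in [1, K={K}], got {I}")
    ks, y1, y2 = _sorted_arrays(paired)
    c1 = np.concatenate([[0.0], np.cumsum(y1)])
    c2 = np.concatenate([[0.0], np.cumsum(y2)])
    j = np.arange(K - I + 1)
    s1 = c1[j + I] - c1[j]
    s2 = c2[j + I] - c2[j]
    good = s1 > 0
    if not good.any():
        raise ValueError("all windows have zero year-1 sums")
    return float(np.mean(s2[good] / s1[good]))
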