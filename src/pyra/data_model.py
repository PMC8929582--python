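"""Core domain types for gap-tolerant detection time series.

Static acoustic monitors (C-PODs and similar click loggers) produce one
detection metric per site-day — clicks/day, detection-positive minutes/day
(DPM/day) or DPM per aggregation period — together with a record of how much
of the day the instrument was actually logging.  Year-on-year trend
estimation by paired ratios only ever compares the *same position within the
annual cycle* across successive cycles, so the central bookkeeping problem
is a day index that stays aligned across years.  Two conventions make that
work:

* the extra day of each leap year (29 February) is dropped before indexing,
  so every cycle is exactly ``C`` units long;
* a missing day is the *absence* of a record, never a recorded zero — a zero
  is a real observation of no detections.

Cycles are anchored at the first record's date (periods of ``C`` units from
deployment start), not at calendar 1 January, because deployments typically
begin mid-year.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CycleConfig",
    "DetectionDay",
    "DailySeries",
    "ValidationReport",
    "strip_leap_days",
    "validate_series",
    "aggregate_periods",
    "load_detections_csv",
    "write_detections_csv",
    "synthetic_dates",
]

#: minutes in a day, used to convert a ``logged_minutes`` column
MINUTES_PER_DAY = 1440.0


@dataclasses.dataclass(frozen=True)
class CycleConfig:
    """Length and unit of the periodic cycle over which positions are matched.

    Parameters
    ----------
    C:
        Cycle length in time units: 365 for daily data, 12 for monthly.
    unit:
        Label for the time unit ("day", "month", "period", ...).
    full_log_threshold:
        Minimum ``logged_fraction`` for a unit to count as *fully logged*
        and therefore eligible for pairing.  Default 1.0 (only whole days
        of logging are used); lower it for sensor clocks that log e.g.
        1439/1440 minutes.
    """

    C: int = 365
    unit: str = "day"
    full_log_threshold: float = 1.0

    def __post_init__(self) -> None:
        if int(self.C) != self.C or self.C < 2:
            raise ValueError(f"cycle length C must be an integer >= 2, got {self.C}")
        if not (0.0 < self.full_log_threshold <= 1.0):
            raise ValueError(
                f"full_log_threshold must lie in (0, 1], got {self.full_log_threshold}"
            )


@dataclasses.dataclass(frozen=True)
class DetectionDay:
    """One site-day observation."""

    site_id: str
    day_index: int
    value: float
    logged_fraction: float
    cycle_index: int
    day_of_cycle: int
    date: object | None = None  # datetime.date when known


class DailySeries:
    """An ordered single-site series of detection-day records.

    Records are stored as parallel arrays sorted strictly increasing in
    ``day_index``; gaps in monitoring are gaps in ``day_index``.
    """

    def __init__(
        self,
        site_id: str,
        cycle_config: CycleConfig,
        day_index: np.ndarray,
        value: np.ndarray,
        logged_fraction: np.ndarray,
        date: np.ndarray | None = None,
    ) -> None:
        self.site_id = str(site_id)
        self.cycle_config = cycle_config
        self.day_index = np.asarray(day_index, dtype=np.int64)
        self.value = np.asarray(value, dtype=float)
        self.logged_fraction = np.asarray(logged_fraction, dtype=float)
        self.date = None if date is None else np.asarray(date, dtype="datetime64[D]")

        n = len(self.day_index)
        if not (len(self.value) == len(self.logged_fraction) == n):
            raise ValueError("day_index, value and logged_fraction must have equal length")
        if self.date is not None and len(self.date) != n:
            raise ValueError("date array length mismatch")
        if n:
            if self.day_index.min() < 1:
                raise ValueError("day_index must be >= 1")
            d = np.diff(self.day_index)
            if np.any(d <= 0):
                where = int(self.day_index[1:][d <= 0][0])
                raise ValueError(
                    f"records must be strictly increasing in day_index "
                    f"(duplicate or unsorted at day_index {where})"
                )
        lf = self.logged_fraction
        if np.any((lf < 0) | (lf > 1)):
            raise ValueError("logged_fraction must lie in [0, 1]")

    # ------------------------------------------------------------------ views
    def __len__(self) -> int:
        return len(self.day_index)

    @property
    def C(self) -> int:
        return self.cycle_config.C

    @property
    def cycle_index(self) -> np.ndarray:
        return (self.day_index - 1) // self.C + 1

    @property
    def day_of_cycle(self) -> np.ndarray:
        return (self.day_index - 1) % self.C + 1

    @property
    def n_cycles(self) -> int:
        """Number of C-length cycles spanned (from day 1 of the anchor)."""
        return 0 if len(self) == 0 else int(np.ceil(self.day_index.max() / self.C))

    @property
    def fully_logged(self) -> np.ndarray:
        return self.logged_fraction >= self.cycle_config.full_log_threshold

    def __iter__(self) -> Iterator[DetectionDay]:
        cyc = self.cycle_index
        doc = self.day_of_cycle
        for i in range(len(self)):
            yield DetectionDay(
                site_id=self.site_id,
                day_index=int(self.day_index[i]),
                value=float(self.value[i]),
                logged_fraction=float(self.logged_fraction[i]),
                cycle_index=int(cyc[i]),
                day_of_cycle=int(doc[i]),
                date=None if self.date is None else self.date[i].astype(object),
            )

    def subset(self, mask: np.ndarray) -> "DailySeries":
        """A new series restricted to ``mask`` (boolean or index array)."""
        return DailySeries(
            self.site_id,
            self.cycle_config,
            self.day_index[mask],
            self.value[mask],
            self.logged_fraction[mask],
            None if self.date is None else self.date[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "site_id": self.site_id,
                "day_index": self.day_index,
                "cycle_index": self.cycle_index,
                "day_of_cycle": self.day_of_cycle,
                "value": self.value,
                "logged_fraction": self.logged_fraction,
            }
        )
        if self.date is not None:
            frame.insert(1, "date", self.date)
        return frame

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"DailySeries(site_id={self.site_id!r}, n={len(self)}, "
            f"C={self.C}, unit={self.cycle_config.unit!r})"
        )


# --------------------------------------------------------------------- input


def strip_leap_days(
    records: pd.DataFrame | Iterable[Mapping],
    cycle_config: CycleConfig | None = None,
    site_id: str | None = None,
) -> DailySeries:
    """Build a :class:`DailySeries` from dated records, dropping 29 February.

    ``records`` must provide ``date`` and ``value`` columns plus either
    ``logged_fraction`` or ``logged_minutes`` (converted by /1440; both
    absent means fully logged).  Every 29 February record is removed and the
    remaining records are renumbered with a ``day_index`` that counts
    calendar days from the first retained date, skipping any intervening
    29 Februaries — so day-of-cycle alignment across years is preserved even
    across gaps.

    Raises
    ------
    ValueError
        On unparseable dates or duplicate site-dates, naming the offender.
    """
    cfg = cycle_config or CycleConfig()
    df = pd.DataFrame(records)
    if df.empty:
        raise ValueError("no records supplied")
    for col in ("date", "value"):
        if col not in df.columns:
            raise ValueError(f"records are missing required column {col!r}")
    if site_id is None:
        if "site_id" in df.columns:
            sites = df["site_id"].astype(str).unique()
            if len(sites) > 1:
                raise ValueError(
                    f"strip_leap_days expects a single site, got {sorted(sites)}; "
                    "use load_detections_csv for multi-site input"
                )
            site_id = sites[0]
        else:
            site_id = "site"

    try:
        dates = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError):
        try:
            dates = pd.to_datetime(df["date"], format="mixed", dayfirst=False)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"unparseable date in input: {exc}") from None
    if dates.duplicated().any():
        bad = dates[dates.duplicated()].iloc[0]
        raise ValueError(f"duplicate record for site {site_id!r} on {bad.date()}")

    if "logged_fraction" in df.columns:
        lf = pd.to_numeric(df["logged_fraction"]).to_numpy(float)
    elif "logged_minutes" in df.columns:
        lf = pd.to_numeric(df["logged_minutes"]).to_numpy(float) / MINUTES_PER_DAY
    else:
        lf = np.ones(len(df))

    order = np.argsort(dates.to_numpy())
    dates = dates.iloc[order].reset_index(drop=True)
    values = pd.to_numeric(df["value"]).to_numpy(float)[order]
    lf = lf[order]

    keep = ~((dates.dt.month == 2) & (dates.dt.day == 29)).to_numpy()
    dates, values, lf = dates[keep].reset_index(drop=True), values[keep], lf[keep]
    if len(dates) == 0:
        raise ValueError("all records fell on 29 February; nothing left")

    # day_index = position in the leap-stripped calendar from the first date
    calendar = pd.date_range(dates.iloc[0], dates.iloc[-1], freq="D")
    calendar = calendar[~((calendar.month == 2) & (calendar.day == 29))]
    lookup = pd.Series(np.arange(1, len(calendar) + 1), index=calendar)
    day_index = lookup.loc[dates].to_numpy(np.int64)

    return DailySeries(
        site_id, cfg, day_index, values, lf, date=dates.to_numpy(dtype="datetime64[D]")
    )


def load_detections_csv(
    path, cycle_config: CycleConfig | None = None
) -> dict[str, DailySeries]:
    """Read the standard input dialect into per-site series.

    Columns: ``site_id``, ``date`` (ISO-8601), ``value`` and either
    ``logged_fraction`` or ``logged_minutes``.  Header required, UTF-8.
    """
    df = pd.read_csv(path, encoding="utf-8")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if "site_id" not in df.columns:
        df["site_id"] = "site"
    out: dict[str, DailySeries] = {}
    for site, grp in df.groupby("site_id", sort=True):
        out[str(site)] = strip_leap_days(grp, cycle_config, site_id=str(site))
    return out


def write_detections_csv(series: DailySeries, path, start_date: str = "2001-01-01") -> None:
    """Write a series in the standard input dialect.

    A series that carries no calendar dates (synthetic data) is assigned
    dates from ``start_date`` onward, skipping 29 Februaries so that a
    round trip through :func:`strip_leap_days` recovers the same day_index.
    """
    dates = series.date
    if dates is None:
        dates = synthetic_dates(series.day_index, start_date)
    pd.DataFrame(
        {
            "site_id": series.site_id,
            "date": pd.Series(dates).dt.strftime("%Y-%m-%d"),
            "value": series.value,
            "logged_fraction": series.logged_fraction,
        }
    ).to_csv(path, index=False)


def synthetic_dates(day_index: np.ndarray, start_date: str = "2001-01-01") -> np.ndarray:
    """Calendar dates for 1-based day indices on a leap-stripped calendar."""
    day_index = np.asarray(day_index, dtype=np.int64)
    n = int(day_index.max())
    # generous span: every stretch of 366 calendar days holds >= 365 usable ones
    calendar = pd.date_range(start_date, periods=n + n // 365 + 2, freq="D")
    calendar = calendar[~((calendar.month == 2) & (calendar.day == 29))]
    return calendar[day_index - 1].to_numpy(dtype="datetime64[D]")


# ---------------------------------------------------------------- validation


@dataclasses.dataclass
class ValidationReport:
    """Pure report on a series; the caller decides what is fatal."""

    site_id: str
    n_records: int
    n_fully_logged: int
    n_cycles: int
    span: int
    gap_runs: list[int]
    errors: list[str]

    @property
    def ok(self) -> bool:
        return not self.errors

    @property
    def n_missing(self) -> int:
        return int(sum(self.gap_runs))


def validate_series(series: DailySeries) -> ValidationReport:
    """Report logging completeness, gap structure and value problems."""
    errors: list[str] = []
    bad_nan = np.flatnonzero(~np.isfinite(series.value))
    for i in bad_nan[:10]:
        errors.append(f"non-finite value at day_index {int(series.day_index[i])}")
    bad_neg = np.flatnonzero(np.isfinite(series.value) & (series.value < 0))
    for i in bad_neg[:10]:
        errors.append(
            f"negative value {series.value[i]:g} at day_index {int(series.day_index[i])}"
        )
    gaps = []
    if len(series) > 1:
        d = np.diff(series.day_index)
        gaps = [int(g - 1) for g in d[d > 1]]
    span = 0 if len(series) == 0 else int(series.day_index.max() - series.day_index.min() + 1)
    return ValidationReport(
        site_id=series.site_id,
        n_records=len(series),
        n_fully_logged=int(series.fully_logged.sum()),
        n_cycles=series.n_cycles,
        span=span,
        gap_runs=gaps,
        errors=errors,
    )


# --------------------------------------------------------------- aggregation


def aggregate_periods(
    series: DailySeries,
    period_length: int,
    bin_log_threshold: float = 0.5,
    new_C: int | None = None,
) -> DailySeries:
    """Aggregate a daily series into consecutive fixed-length periods.

    Non-overlapping bins of ``period_length`` days are laid over the
    day-index axis (bin ``b`` covers days ``(b-1)*L+1 .. b*L``).  A bin's
    value is the *mean over its fully logged days*; its logged_fraction is
    the fraction of its days that were fully logged; bins containing no
    fully logged day are absent from the output.

    The returned series uses unit ``"period"`` with cycle length
    ``new_C`` (default ``round(C / period_length)``, e.g. 12 for 30-day
    periods on an annual cycle) and ``full_log_threshold=bin_log_threshold``
    so that downstream pairing treats a bin as usable when at least that
    fraction of its days was monitored.
    """
    L = int(period_length)
    if L < 1:
        raise ValueError("period_length must be >= 1")
    if new_C is None:
        new_C = max(2, round(series.C / L))
    bins = (series.day_index - 1) // L + 1
    full = series.fully_logged
    out_bin, out_val, out_lf = [], [], []
    for b in np.unique(bins):
        m = (bins == b) & full
        n_full = int(m.sum())
        if n_full == 0:
            continue
        out_bin.append(int(b))
        out_val.append(float(series.value[m].mean()))
        out_lf.append(n_full / L)
    cfg = CycleConfig(C=new_C, unit="period", full_log_threshold=bin_log_threshold)
    return DailySeries(
        series.site_id,
        cfg,
        np.array(out_bin, dtype=np.int64),
        np.array(out_val),
        np.array(out_lf),
    )
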