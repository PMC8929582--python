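"""Paired-data extraction and multi-site pooling.

The paired-ratio method compares only those day positions that were fully
logged at the *same position within the cycle* in two successive cycles.
Pairs are always formed between consecutive cycles (j, j+1), never across
longer lags; a day fully logged in three consecutive cycles therefore
appears in two pairs, once as the second member and once as the first.

Multi-site pooling note
-----------------------
Regional estimates pool pairs across sites by summing year-1 detections over
all sites and likewise year-2.  Sites are aligned by *day-of-cycle position*
(day_index), not by calendar date: all sites must share the same cycle
anchoring for the pooled ratio to be meaningful.  This is the implicit
convention of summing per-site detections within a common two-year window.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .data_model import CycleConfig, DailySeries

__all__ = [
    "PairedObservation",
    "PairedSeries",
    "pair_extract",
    "paired_days",
    "days_logged_in_all_cycles",
    "combine_sites",
]


@dataclasses.dataclass(frozen=True)
class PairedObservation:
    """A matched (year-1, year-2) value pair at one day-of-cycle position.

    ``k`` is the day_index of the year-1 member; the year-2 member sits
    exactly C units later.
    """

    site_id: str
    day_of_cycle: int
    k: int
    y1: float
    y2: float
    pair_cycle: int


class PairedSeries:
    """An ordered collection of paired observations.

    Freshly extracted series are sorted by (pair_cycle, day_of_cycle) — i.e.
    by ``k`` — with ties across sites broken by site_id.  Bootstrap
    resamples reuse this container with pairs in draw order and possible
    repetition, so ordering and uniqueness are conventions of the
    constructors, not hard invariants of the container.
    """

    def __init__(
        self,
        cycle_config: CycleConfig,
        site_id: np.ndarray | Sequence[str],
        k: np.ndarray,
        y1: np.ndarray,
        y2: np.ndarray,
    ) -> None:
        self.cycle_config = cycle_config
        self.site_id = np.asarray(site_id, dtype=object)
        self.k = np.asarray(k, dtype=np.int64)
        self.y1 = np.asarray(y1, dtype=float)
        self.y2 = np.asarray(y2, dtype=float)
        n = len(self.k)
        if not (len(self.site_id) == len(self.y1) == len(self.y2) == n):
            raise ValueError("site_id, k, y1, y2 must have equal length")
        if np.any(self.y1 < 0) or np.any(self.y2 < 0):
            raise ValueError("paired values must be >= 0")

    @property
    def K(self) -> int:
        """Total number of paired data points."""
        return len(self.k)

    def __len__(self) -> int:
        return self.K

    @property
    def C(self) -> int:
        return self.cycle_config.C

    @property
    def pair_cycle(self) -> np.ndarray:
        return (self.k - 1) // self.C + 1

    @property
    def day_of_cycle(self) -> np.ndarray:
        return (self.k - 1) % self.C + 1

    def __iter__(self) -> Iterator[PairedObservation]:
        pc, doc = self.pair_cycle, self.day_of_cycle
        for i in range(self.K):
            yield PairedObservation(
                site_id=str(self.site_id[i]),
                day_of_cycle=int(doc[i]),
                k=int(self.k[i]),
                y1=float(self.y1[i]),
                y2=float(self.y2[i]),
                pair_cycle=int(pc[i]),
            )

    def take(self, idx: np.ndarray) -> "PairedSeries":
        """Pairs at ``idx`` in the given order (duplicates allowed)."""
        return PairedSeries(
            self.cycle_config, self.site_id[idx], self.k[idx], self.y1[idx], self.y2[idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": self.site_id,
                "pair_cycle": self.pair_cycle,
                "day_of_cycle": self.day_of_cycle,
                "y1": self.y1,
                "y2": self.y2,
            }
        )

    def write_csv(self, path) -> None:
        """Audit export: one row per pair."""
        self.to_frame().to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        sites = sorted(set(self.site_id.tolist()))
        return f"PairedSeries(K={self.K}, C={self.C}, sites={sites})"


def pair_extract(series: DailySeries) -> PairedSeries:
    """Extract all consecutive-cycle pairs of fully logged day positions.

    For every day position ``d`` fully logged with value ``y1`` whose
    counterpart ``d + C`` (same day-of-cycle, next cycle) is also fully
    logged with value ``y2``, a pair (y1, y2) is emitted.  Invariant to the
    input record order and to the removal of unpaired days.
    """
    C = series.C
    full = series.fully_logged
    d = series.day_index[full]
    v = series.value[full]
    if len(d) == 0:
        warnings.warn(f"site {series.site_id!r}: no fully logged days; no pairs")
        return PairedSeries(series.cycle_config, [], [], [], [])

    pos = np.searchsorted(d, d + C)
    pos_c = np.clip(pos, 0, len(d) - 1)
    match = (pos < len(d)) & (d[pos_c] == d + C)
    if not match.any():
        warnings.warn(
            f"site {series.site_id!r}: span {int(d.max() - d.min() + 1)} units "
            f"yields no day position fully logged in two successive cycles"
        )
    k = d[match]
    return PairedSeries(
        series.cycle_config,
        np.full(int(match.sum()), series.site_id, dtype=object),
        k,
        v[match],
        v[pos_c[match]],
    )


def paired_days(series: DailySeries) -> DailySeries:
    """The sub-series of distinct days participating in at least one pair.

    This is the "paired data" categorisation of a gappy series: the union of
    year-1 and year-2 members over all pairs, each day counted once.
    """
    pairs = pair_extract(series)
    used = np.union1d(pairs.k, pairs.k + series.C)
    mask = np.isin(series.day_index, used)
    return series.subset(mask)


def days_logged_in_all_cycles(series: DailySeries, n_cycles: int) -> int:
    """Count day-of-cycle positions fully logged in every one of the first
    ``n_cycles`` cycles."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if series.n_cycles < n_cycles:
        raise ValueError(
            f"series spans {series.n_cycles} cycles, fewer than requested {n_cycles}"
        )
    full = series.fully_logged
    cyc = series.cycle_index[full]
    doc = series.day_of_cycle[full]
    common: set[int] | None = None
    for j in range(1, n_cycles + 1):
        positions = set(doc[cyc == j].tolist())
        common = positions if common is None else common & positions
        if not common:
            return 0
    return len(common) if common else 0


def combine_sites(per_site: Iterable[PairedSeries]) -> PairedSeries:
    """Pool paired series from several sites into a regional series.

    The pooled series is the concatenation of all sites' pairs, ordered by
    (pair_cycle, day_of_cycle, site).  Downstream ratios sum y1 and y2 over
    the pooled collection, which equals summing per-site totals first.  All
    sites must share the same cycle length (and hence anchoring convention).
    """
    series = list(per_site)
    if not series:
        raise ValueError("combine_sites needs at least one PairedSeries")
    C0 = series[0].cycle_config.C
    for s in series[1:]:
        if s.cycle_config.C != C0:
            raise ValueError(
                f"mismatched cycle lengths in combine_sites: {C0} vs {s.cycle_config.C}"
            )
    site = np.concatenate([s.site_id for s in series]) if series else np.array([], object)
    k = np.concatenate([s.k for s in series])
    y1 = np.concatenate([s.y1 for s in series])
    y2 = np.concatenate([s.y2 for s in series])

    key = np.array([f"{kk:012d}|{ss}" for kk, ss in zip(k, site)])
    if len(np.unique(key)) != len(key):
        dup = pd.Series(key).value_counts()
        bad = dup[dup > 1].index[0]
        raise ValueError(f"duplicate (site, position) pair in combine_sites: {bad}")
    order = np.argsort(key, kind="stable")
    return PairedSeries(series[0].cycle_config, site[order], k[order], y1[order], y2[order])
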