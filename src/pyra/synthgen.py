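"""Synthetic scenario generators for benchmarking trend estimation.

Two extreme study designs exercise the confounding that gappy seasonal data
create:

* **Scenario 1 — seasonal, no trend**: the daily mean drops linearly within
  each cycle from ``start_mean`` to ``end_mean_within_cycle`` and resets at
  each cycle boundary.  There is no cross-year change, so any trend an
  estimator reports is an artefact.
* **Scenario 2 — uniform decline**: the daily mean falls linearly across the
  whole span, from ``start_mean`` on day 1 to
  ``start_mean × (1 − total_decline_fraction)`` on the last day, with no
  seasonality.

Daily fluctuations are Normal about the mean (truncated at zero: detection
counts are non-negative).  The gap design retains, in cycle ``j``, only a
``window_length``-day observation window that shifts forward by
``window_shift`` days per cycle — a drifting gap pattern that correlates
with season and is precisely what defeats naive trend fits.  With the
default 100-day window shifting 30 days per cycle over 4 × 365 days this
leaves 400 logged days (27%), 70 paired positions per successive cycle
pair, 340 distinct paired days (23%) and only 10 positions logged in all
four cycles.

Noise presets differ by scenario.  Scenario 1 uses low/moderate/high
s.d. = 5/15/30 against a 50-unit seasonal ramp.  Scenario 2 uses 1/2/4:
its defining property is a cross-year decline that *dominates* the daily
noise — the paired series splits cleanly above/below its median — and with
a 75-unit total decline that requires daily noise of only a few units.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple

import numpy as np

from .data_model import CycleConfig, DailySeries
from .pairing import PairedSeries, pair_extract

__all__ = [
    "ScenarioConfig",
    "Triplet",
    "NOISE_PRESETS",
    "scenario1",
    "scenario2",
    "mean_function",
    "gen_complete",
    "apply_window_design",
    "make_triplet",
]

SCENARIOS = ("S1_seasonal_no_trend", "S2_uniform_decline")

#: named noise levels per scenario (daily Normal s.d. in detection units)
NOISE_PRESETS = {
    "S1_seasonal_no_trend": {"low": 5.0, "moderate": 15.0, "high": 30.0},
    "S2_uniform_decline": {"low": 1.0, "moderate": 2.0, "high": 4.0},
}


@dataclasses.dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterisation of a synthetic scenario and its gap design."""

    scenario: str
    n_cycles: int = 4
    C: int = 365
    start_mean: float = 100.0
    end_mean_within_cycle: float = 50.0  # Scenario 1 only
    total_decline_fraction: float = 0.75  # Scenario 2 only
    noise_sd: float = 15.0
    truncate_at_zero: bool = True
    window_length: int = 100
    window_shift: int = 30
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.C < 2:
            raise ValueError("C must be >= 2")
        if self.start_mean <= 0:
            raise ValueError("start_mean must be > 0")
        if self.end_mean_within_cycle < 0:
            raise ValueError("end_mean_within_cycle must be >= 0")
        if not (0.0 <= self.total_decline_fraction < 1.0):
            raise ValueError("total_decline_fraction must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.window_length < 1 or self.window_shift < 0:
            raise ValueError("window_length must be >= 1 and window_shift >= 0")
        if self.window_length + (self.n_cycles - 1) * self.window_shift > self.C:
            raise ValueError(
                "window design exceeds cycle bounds: "
                f"window_length + (n_cycles-1)*window_shift = "
                f"{self.window_length + (self.n_cycles - 1) * self.window_shift} > C={self.C}"
            )

    @property
    def n_days(self) -> int:
        return self.n_cycles * self.C

    @property
    def cycle_config(self) -> CycleConfig:
        return CycleConfig(C=self.C, unit="day", full_log_threshold=1.0)


class Triplet(NamedTuple):
    """The three categorisations drawn from one seeded realisation."""

    complete: DailySeries
    incomplete: DailySeries
    paired: PairedSeries


def scenario1(noise: str = "moderate", seed: int | None = None, **overrides) -> ScenarioConfig:
    """Seasonal-ramp, no-cross-year-trend configuration at a named noise level."""
    overrides.setdefault("noise_sd", NOISE_PRESETS["S1_seasonal_no_trend"][noise])
    return ScenarioConfig(scenario="S1_seasonal_no_trend", seed=seed, **overrides)


def scenario2(noise: str = "moderate", seed: int | None = None, **overrides) -> ScenarioConfig:
    """Uniform-decline configuration at a named noise level."""
    overrides.setdefault("noise_sd", NOISE_PRESETS["S2_uniform_decline"][noise])
    return ScenarioConfig(scenario="S2_uniform_decline", seed=seed, **overrides)


def mean_function(config: ScenarioConfig, day_index: np.ndarray) -> np.ndarray:
    """The deterministic daily mean μ(d) for 1-based day indices."""
    d = np.asarray(day_index, dtype=float)
    if config.scenario == "S1_seasonal_no_trend":
        doc = (d - 1) % config.C  # 0 .. C-1 within each cycle
        slope = (config.end_mean_within_cycle - config.start_mean) / (config.C - 1)
        return config.start_mean + slope * doc
    # S2: linear from start_mean at day 1 to start_mean*(1-f) at the last day
    span = config.n_days - 1
    decline = config.start_mean * config.total_decline_fraction
    return config.start_mean - decline * (d - 1) / span


def gen_complete(config: ScenarioConfig) -> DailySeries:
    """The fully logged series: n_cycles × C days of seeded Normal draws."""
    d = np.arange(1, config.n_days + 1)
    mu = mean_function(config, d)
    rng = np.random.default_rng(config.seed)
    values = rng.normal(mu, config.noise_sd) if config.noise_sd > 0 else mu.copy()
    if config.truncate_at_zero:
        values = np.maximum(values, 0.0)
    return DailySeries(
        site_id="synthetic",
        cycle_config=config.cycle_config,
        day_index=d,
        value=values,
        logged_fraction=np.ones(config.n_days),
    )


def apply_window_design(complete: DailySeries, config: ScenarioConfig) -> DailySeries:
    """Impose the shifting observation-window gap design.

    Cycle ``j`` retains only day-of-cycle positions in
    ``[1 + (j−1)·shift, (j−1)·shift + window_length]``; all other days are
    removed (absent, not zeroed).
    """
    last = (config.n_cycles - 1) * config.window_shift + config.window_length
    if last > config.C:
        raise ValueError("observation window exceeds cycle bounds")
    cyc = complete.cycle_index
    doc = complete.day_of_cycle
    lo = 1 + (cyc - 1) * config.window_shift
    hi = (cyc - 1) * config.window_shift + config.window_length
    return complete.subset((doc >= lo) & (doc <= hi))


def make_triplet(config: ScenarioConfig) -> Triplet:
    """Complete, incomplete and paired data from one seeded draw."""
    complete = gen_complete(config)
    incomplete = apply_window_design(complete, config)
    return Triplet(complete, incomplete, pair_extract(incomplete))
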