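"""Nonparametric randomisation trend tests.

A randomisation (permutation) trend test treats the observed time series as
one draw from the uniform distribution over all reorderings of its values
and asks whether a trend-sensitive statistic is extreme against that null.
Gaps and missing data do not affect validity.  Four classical statistics are
provided:

RT1  linear-trend test: OLS regression slope of value on time.
RT2  runs above/below the median: values equal to the median are removed;
     the statistic is the number of maximal runs of above/below signs.  A
     low count indicates a trend (long runs above then below).
RT3  signs test: the number of positive successive differences
     ``y[i+1] − y[i] > 0``; low indicates decline, high indicates increase.
RT4  runs up/down: zero differences are removed; the statistic is the
     number of maximal runs of same-sign differences.  A low count
     indicates a trend.

p-values use the add-one correction ``p = (1 + extreme) / (B + 1)`` so they
are never zero, with tails matching each statistic's directional reading:
two-sided on |slope| for RT1, lower for RT2 and RT4, two-sided about the
exact null mean (n-1)/2 for RT3.  All tails can be overridden.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats as _sps

__all__ = [
    "RandTestResult",
    "stat_linear_slope",
    "stat_runs_median",
    "stat_positive_diffs",
    "stat_runs_updown",
    "randomisation_test",
    "randomisation_table",
    "TEST_IDS",
    "DEFAULT_TAILS",
]

TEST_IDS = ("RT1", "RT2", "RT3", "RT4")

#: default tail convention per test (overridable per call)
DEFAULT_TAILS = {
    "RT1": "two_sided",
    "RT2": "lower",
    "RT3": "two_sided",
    "RT4": "lower",
}


@dataclasses.dataclass(frozen=True)
class RandTestResult:
    """Outcome of one randomisation trend test."""

    test_id: str
    statistic: float
    p_value: float
    B: int
    tail: str
    n: int
    seed: int | None


# ------------------------------------------------------------ scalar statistics


def _runs(signs: np.ndarray) -> int:
    """Number of maximal runs in a 1-D array of nonzero signs."""
    if len(signs) == 0:
        return 0
    return int(1 + np.count_nonzero(signs[1:] != signs[:-1]))


def stat_linear_slope(values: np.ndarray, times: np.ndarray | None = None) -> float:
    """OLS slope of value on time (RT1 statistic)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("linear slope needs n >= 3")
    t = np.arange(1.0, len(v) + 1) if times is None else np.asarray(times, dtype=float)
    if len(t) != len(v):
        raise ValueError("times and values must have equal length")
    if np.ptp(t) == 0:
        raise ValueError("degenerate times: all observation times equal")
    return float(_sps.linregress(t, v).slope)


def stat_runs_median(values: np.ndarray) -> int:
    """Number of runs above and below the median (RT2 statistic)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("runs-above/below-median needs n >= 3")
    med = np.median(v)
    signs = np.sign(v - med)
    signs = signs[signs != 0]
    if len(signs) == 0:
        raise ValueError("statistic undefined: all values equal the median")
    return _runs(signs)


def stat_positive_diffs(values: np.ndarray) -> int:
    """Number of positive successive differences (RT3 statistic)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("positive-differences count needs n >= 2")
    return int(np.count_nonzero(np.diff(v) > 0))


def stat_runs_updown(values: np.ndarray) -> int:
    """Number of runs of same-sign successive differences (RT4 statistic)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("runs-up/down needs n >= 3")
    signs = np.sign(np.diff(v))
    signs = signs[signs != 0]
    if len(signs) == 0:
        raise ValueError("statistic undefined: all successive differences are zero")
    return _runs(signs)


_SCALAR_STATS = {
    "RT1": stat_linear_slope,
    "RT2": stat_runs_median,
    "RT3": stat_positive_diffs,
    "RT4": stat_runs_updown,
}


# ------------------------------------------------------------- batch machinery


def _batch_runs(signs: np.ndarray) -> np.ndarray:
    """Run counts per row of a sign matrix, zeros removed within each row."""
    B, n = signs.shape
    nz = signs != 0
    pos = np.where(nz, np.arange(n)[None, :], -1)
    np.maximum.accumulate(pos, axis=1, out=pos)
    filled = np.take_along_axis(signs, np.maximum(pos, 0), axis=1)
    filled = np.where(pos >= 0, filled, 0)
    # a new run starts where a nonzero sign differs from the last nonzero sign
    changes = nz[:, 1:] & (filled[:, :-1] != 0) & (signs[:, 1:] != filled[:, :-1])
    return changes.sum(axis=1) + nz.any(axis=1).astype(np.int64)


def _perm_matrix(values: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    return rng.permuted(np.tile(values, (B, 1)), axis=1)


def _batch_stats(
    mat: np.ndarray,
    test_id: str,
    times: np.ndarray | None = None,
    median: float | None = None,
) -> np.ndarray:
    """The chosen statistic evaluated on every row of a permutation matrix."""
    if test_id == "RT1":
        t = np.arange(1.0, mat.shape[1] + 1) if times is None else np.asarray(times, float)
        tc = t - t.mean()
        return (mat @ tc) / (tc @ tc)
    if test_id == "RT2":
        med = float(np.median(mat[0])) if median is None else median
        return _batch_runs(np.sign(mat - med))
    if test_id == "RT3":
        return (np.diff(mat, axis=1) > 0).sum(axis=1)
    if test_id == "RT4":
        return _batch_runs(np.sign(np.diff(mat, axis=1)))
    raise ValueError(f"unknown test_id {test_id!r}")


def _p_value(observed: float, perm: np.ndarray, tail: str, centre: float = 0.0) -> float:
    B = len(perm)
    if tail == "lower":
        extreme = np.count_nonzero(perm <= observed)
    elif tail == "upper":
        extreme = np.count_nonzero(perm >= observed)
    elif tail == "two_sided":
        extreme = np.count_nonzero(np.abs(perm - centre) >= abs(observed - centre))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + int(extreme)) / (B + 1)


def _null_centre(test_id: str, n: int, perm: np.ndarray) -> float:
    """Centre for two-sided distances.

    The slope is symmetric about 0 under exchangeability.  The positive-
    difference count has exact null mean (n-1)/2 for distinct values; using
    the closed form rather than the empirical permutation mean keeps the
    "at least as extreme" rule deterministic when the observed statistic is
    exactly equidistant from the centre (integer statistics, half-integer
    centre).  The runs statistics fall back to the empirical mean.
    """
    if test_id == "RT1":
        return 0.0
    if test_id == "RT3":
        return (n - 1) / 2.0
    return float(perm.mean())


# ----------------------------------------------------------------- public API


def randomisation_test(
    values: np.ndarray,
    test_id: str,
    B: int = 5000,
    seed: int | None = None,
    times: np.ndarray | None = None,
    tail: str | None = None,
) -> RandTestResult:
    """Permutation p-value for one trend statistic.

    ``B`` random reorderings of the values (observation times stay fixed)
    form the randomisation distribution; the p-value is the add-one-
    corrected share of reorderings at least as extreme as the observed
    statistic under the test's tail convention.
    """
    if test_id not in TEST_IDS:
        raise ValueError(f"unknown test_id {test_id!r}; expected one of {TEST_IDS}")
    v = np.asarray(values, dtype=float)
    tail = tail or DEFAULT_TAILS[test_id]
    rng = np.random.default_rng(seed)

    if test_id == "RT1":
        observed = stat_linear_slope(v, times)
        perm = _batch_stats(_perm_matrix(v, B, rng), "RT1", times=times)
    elif test_id == "RT2":
        observed = float(stat_runs_median(v))
        med = float(np.median(v))
        kept = v[v != med]  # dropping median-equal values commutes with permuting
        perm = _batch_stats(_perm_matrix(kept, B, rng), "RT2", median=med)
    else:
        observed = float(_SCALAR_STATS[test_id](v))
        perm = _batch_stats(_perm_matrix(v, B, rng), test_id)

    centre = _null_centre(test_id, len(v), perm)
    return RandTestResult(
        test_id=test_id,
        statistic=observed,
        p_value=_p_value(observed, perm, tail, centre),
        B=B,
        tail=tail,
        n=len(v),
        seed=seed,
    )


def randomisation_table(
    values: np.ndarray,
    B: int = 5000,
    seed: int | None = None,
    times: np.ndarray | None = None,
) -> dict[str, RandTestResult]:
    """All four trend tests on one series, sharing a permutation stream."""
    return {
        tid: randomisation_test(values, tid, B=B, seed=seed, times=times)
        for tid in TEST_IDS
    }
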