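"""Simulation envelopes, deviating intervals and rank goodness-of-fit tests.

An *envelope* is the pointwise minimum/maximum band of a summary function
over ``n_sims`` (default 499) null-model simulations.  Distance intervals
where the observed function leaves the band are candidate departures, but
because the band's pointwise coverage does not control the error rate over
an interval, each candidate is re-tested on an *independent* second batch
of simulations with a Loosmore-Ford style statistic

    u_j = sum_{r_k in interval} (f_j(r_k) - fbar_{-j}(r_k))^2 * dr ,

where fbar_{-j} is the pointwise mean over the other functions
(leave-one-out).  The null is rejected for the interval when the observed
u ranks among the ``k`` highest or ``k`` lowest of all ``n_sims + 1``
values; at the defaults (k = 5, 500 values) the per-tail level is
5/500 = 0.01.  Ties are resolved by treating the observed value as the
more extreme one.

``deviation_strength`` scores a departure as the envelope's displacement
from the null line g = 1 relative to the envelope's width, and
``cluster_scale`` reads the within-cohort cluster diameter off the first
significant above-envelope interval of a univariate PCF analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .summary import SummaryFunction

__all__ = [
    "Envelope",
    "DeviationInterval",
    "DeviationStrength",
    "build_envelope",
    "find_deviation_intervals",
    "gof_test",
    "deviation_strength",
    "cluster_scale",
]


@dataclass
class Envelope:
    """Pointwise min/max/mean band over a batch of simulated functions."""

    r: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    mean: np.ndarray
    n_sims: int
    sims: np.ndarray  # (n_sims, len(r)) simulated values
    observed: SummaryFunction
    valid: np.ndarray  # grid points usable for interval detection


def build_envelope(
    observed: SummaryFunction,
    simulations: Sequence[SummaryFunction],
) -> Envelope:
    """Pointwise min/max/mean over the simulated summary functions.

    All simulations must share the observed function's r grid.  Grid points
    where the observed estimate is unreliable (r < bandwidth) or any value
    is undefined are excluded from interval detection.
    """
    sims = []
    for s in simulations:
        if s.r.shape != observed.r.shape or not np.allclose(s.r, observed.r):
            raise ValueError("simulated function has a different r grid")
        sims.append(s.values)
    if not sims:
        raise ValueError("no simulations supplied")
    mat = np.vstack(sims)
    valid = (
        observed.reliable
        & np.isfinite(observed.values)
        & np.all(np.isfinite(mat), axis=0)
    )
    return Envelope(
        observed.r,
        mat.min(axis=0),
        mat.max(axis=0),
        mat.mean(axis=0),
        mat.shape[0],
        mat,
        observed,
        valid,
    )


@dataclass
class DeviationInterval:
    """A contiguous run of grid points outside the envelope."""

    r_start: float
    r_end: float
    sign: str  # "above" | "below"
    idx_start: int
    idx_end: int  # inclusive
    u_observed: float | None = None
    rank_high: int | None = None
    rank_low: int | None = None
    significant: bool | None = None
    p_one_tail: float | None = None
    p_two_tail: float | None = None


def find_deviation_intervals(
    observed: SummaryFunction,
    envelope: Envelope,
    min_width: int = 2,
) -> list[DeviationInterval]:
    """Maximal runs of r where the observed function exits the band.

    Runs spanning fewer than ``min_width`` grid points are discarded
    (single-point excursions are expected noise at pointwise coverage).
    """
    out: list[DeviationInterval] = []
    for sign, outside in (
        ("above", observed.values > envelope.hi),
        ("below", observed.values < envelope.lo),
    ):
        mask = outside & envelope.valid
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [idx.size - 1]])
        for s, e in zip(starts, ends):
            if e - s + 1 < min_width:
                continue
            out.append(
                DeviationInterval(
                    float(observed.r[idx[s]]),
                    float(observed.r[idx[e]]),
                    sign,
                    int(idx[s]),
                    int(idx[e]),
                )
            )
    out.sort(key=lambda iv: (iv.r_start, iv.sign))
    return out


def loosmore_u(functions: np.ndarray, dr: np.ndarray) -> np.ndarray:
    """Loosmore-Ford u for each row against the leave-one-out column means."""
    m = functions.shape[0]
    if m < 2:
        raise ValueError("need at least two functions")
    col_sum = functions.sum(axis=0)
    loo_mean = (col_sum[None, :] - functions) / (m - 1)
    return ((functions - loo_mean) ** 2 * dr[None, :]).sum(axis=1)


def gof_test(
    interval: DeviationInterval,
    observed: SummaryFunction,
    second_sim_batch: Sequence[SummaryFunction],
    k: int = 5,
) -> DeviationInterval:
    """Rank the observed u against an independent simulation batch.

    Significance: the observed u is among the ``k`` highest or ``k`` lowest
    of the ``n_sims + 1`` values.  Ranks count ties in the observed value's
    favor (observed treated as more extreme).
    """
    r = observed.r
    if interval.idx_start < 0 or interval.idx_end >= r.size:
        raise ValueError("interval lies outside the r grid")
    cols = np.arange(interval.idx_start, interval.idx_end + 1)
    mat = np.vstack(
        [observed.values[cols]] + [s.values[cols] for s in second_sim_batch]
    )
    finite = np.all(np.isfinite(mat), axis=0)
    if not np.any(finite):
        raise ValueError("interval has no usable grid points")
    cols = cols[finite]
    mat = mat[:, finite]
    dr = np.gradient(r)[cols]
    u = loosmore_u(mat, dr)
    u_o, u_i = u[0], u[1:]
    rank_high = 1 + int(np.sum(u_i > u_o))
    rank_low = 1 + int(np.sum(u_i < u_o))
    m = u.size
    return replace(
        interval,
        u_observed=float(u_o),
        rank_high=rank_high,
        rank_low=rank_low,
        significant=(rank_high <= k) or (rank_low <= k),
        p_one_tail=min(rank_high, rank_low) / m,
        p_two_tail=min(1.0, 2.0 * min(rank_high, rank_low) / m),
    )


@dataclass(frozen=True)
class DeviationStrength:
    interval: DeviationInterval
    strength: float
    skipped_points: int = 0


def deviation_strength(
    interval: DeviationInterval, envelope: Envelope
) -> DeviationStrength:
    """Envelope displacement from the null line relative to envelope width.

    Mean over the interval of |nearest bound - 1| / (hi - lo), where the
    nearest bound is the one on the side of the observed excursion.  Grid
    points with a degenerate (zero-width) envelope are skipped; an interval
    whose observed values lie inside the band scores 0.
    """
    cols = np.arange(interval.idx_start, interval.idx_end + 1)
    obs = envelope.observed.values[cols]
    hi, lo = envelope.hi[cols], envelope.lo[cols]
    outside = (obs > hi) if interval.sign == "above" else (obs < lo)
    if not np.any(outside):
        return DeviationStrength(interval, 0.0)
    bound = hi if interval.sign == "above" else lo
    width = hi - lo
    usable = outside & (width > 0)
    skipped = int(np.sum(outside & ~usable))
    if not np.any(usable):
        return DeviationStrength(interval, 0.0, skipped)
    strength = float(np.mean(np.abs(bound[usable] - 1.0) / width[usable]))
    return DeviationStrength(interval, strength, skipped)


def cluster_scale(
    tested_intervals: Sequence[DeviationInterval],
    r: np.ndarray | None = None,
    first_valid_r: float | None = None,
) -> float | None:
    """Within-cohort cluster diameter from a univariate PCF analysis.

    The r at which the first significant above-envelope interval ends,
    provided that interval starts at (or within one grid step of) the
    smallest interpretable distance; ``None`` when no such interval exists.
    """
    sig = [
        iv
        for iv in tested_intervals
        if iv.sign == "above" and iv.significant
    ]
    if not sig:
        return None
    sig.sort(key=lambda iv: iv.r_start)
    first = sig[0]
    step = float(np.median(np.diff(r))) if r is not None and r.size > 1 else np.inf
    origin = first_valid_r if first_valid_r is not None else 0.0
    if first.r_start > origin + step:
        return None
    return float(first.r_end)
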