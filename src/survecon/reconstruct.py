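"""Pseudo individual-patient data from digitized Kaplan-Meier curves.

Published KM curves plus their numbers-at-risk tables carry enough
information to rebuild approximate patient-level (time, event) records:
within each risk-table interval the survival drops pin down the event
counts, and the difference between the at-risk decline and the events
is censoring, assumed spread uniformly over the interval. The expansion
is fully deterministic — censored records are placed at equally spaced
times, never sampled — so everything downstream of a given digitized
curve is reproducible without a seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class ReconstructionError(ValueError):
    """Digitized curve and risk table are mutually inconsistent."""


@dataclass(frozen=True)
class DigitizedKM:
    """A digitized KM curve: (time, survival) points plus numbers at risk.

    ``points`` must start at (0, 1.0) with non-increasing survival;
    ``risk_table`` gives the number of patients still at risk at fixed
    calendar times (non-increasing counts). Times are months.
    """

    points: tuple[tuple[float, float], ...]
    risk_table: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        pts = tuple((float(t), float(s)) for t, s in self.points)
        rt = tuple((float(t), int(n)) for t, n in self.risk_table)
        if not pts or pts[0][0] != 0.0 or abs(pts[0][1] - 1.0) > 1e-9:
            raise ValueError("digitized curve must start at (0, 1.0)")
        times = np.array([t for t, _ in pts])
        surv = np.array([s for _, s in pts])
        if np.any(np.diff(times) < 0):
            raise ValueError("curve times must be sorted ascending")
        if np.any(np.diff(surv) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if np.any((surv < -1e-12) | (surv > 1 + 1e-12)):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if not rt:
            raise ValueError("risk table must be non-empty")
        rtimes = np.array([t for t, _ in rt])
        rcounts = np.array([n for _, n in rt])
        if np.any(np.diff(rtimes) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        if np.any(np.diff(rcounts) > 0):
            raise ValueError("risk counts must be non-increasing")
        if np.any(rcounts < 0):
            raise ValueError("risk counts must be non-negative")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "risk_table", rt)

    def survival_at_points(self) -> np.ndarray:
        return np.array([s for _, s in self.points])

    def to_csv(self, curve_path: str | Path, risk_path: str | Path) -> None:
        """Write the curve and risk table as two CSV files.

        Columns: ``time_months,survival`` and ``time_months,n_at_risk``.
        """
        with open(curve_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_months", "survival"])
            w.writerows(self.points)
        with open(risk_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_months", "n_at_risk"])
            w.writerows(self.risk_table)

    @classmethod
    def from_csv(cls, curve_path: str | Path, risk_path: str | Path) -> "DigitizedKM":
        def read(path, ncol_names):
            with open(path, newline="") as fh:
                rows = list(csv.reader(fh))
            if not rows or [c.strip() for c in rows[0]] != ncol_names:
                raise ValueError(f"{path}: expected header {','.join(ncol_names)}")
            return [tuple(float(v) for v in row) for row in rows[1:] if row]

        pts = read(curve_path, ["time_months", "survival"])
        rt = [(t, int(n)) for t, n in read(risk_path, ["time_months", "n_at_risk"])]
        return cls(tuple(pts), tuple(rt))


@dataclass(frozen=True)
class IntervalCounts:
    """Event/censor bookkeeping per risk-table interval.

    ``event_times``/``event_counts`` give integer events at each
    digitized drop time inside the interval; ``censored`` is the integer
    number censored within the interval. ``n_start`` of each interval
    equals the previous interval's ``n_start - events - censored``.
    """

    intervals: tuple[dict, ...]  # keys: start, end, n_start, event_times,
    # event_counts, censored, administrative (True only for the closing
    # interval after the last risk-table entry)

    @property
    def n_initial(self) -> int:
        return self.intervals[0]["n_start"] if self.intervals else 0

    @property
    def total_events(self) -> int:
        return sum(sum(iv["event_counts"]) for iv in self.intervals)

    @property
    def total_censored(self) -> int:
        """Censored within follow-up (excludes the administrative closure)."""
        return sum(iv["censored"] for iv in self.intervals if not iv["administrative"])

    @property
    def n_remaining(self) -> int:
        """Still at risk at curve end, censored administratively on expansion."""
        return sum(iv["censored"] for iv in self.intervals if iv["administrative"])


@dataclass(frozen=True)
class PseudoIPD:
    """Reconstructed patient-level records: times and 0/1 event flags."""

    times: tuple[float, ...]
    events: tuple[int, ...]

    def __post_init__(self) -> None:
        t = tuple(float(v) for v in self.times)
        e = tuple(int(v) for v in self.events)
        if len(t) != len(e):
            raise ValueError("times and events must have equal length")
        if any(v < 0 for v in t):
            raise ValueError("negative follow-up time")
        if any(v not in (0, 1) for v in e):
            raise ValueError("event flags must be 0 or 1")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(sum(self.events))


def _largest_remainder(real_counts: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative reals to integers summing exactly to ``total``."""
    real_counts = np.maximum(real_counts, 0.0)
    floors = np.floor(real_counts).astype(int)
    short = total - int(floors.sum())
    if short < 0:  # over-allocated by floors (can happen after clipping)
        order = np.argsort(real_counts - floors)  # smallest remainders first
        for idx in order:
            take = min(floors[idx], -short)
            floors[idx] -= take
            short += take
            if short == 0:
                break
        return floors
    remainders = real_counts - floors
    order = np.argsort(-remainders, kind="stable")
    for idx in order[:short]:
        floors[idx] += 1
    return floors


def reconstruct_interval_counts(km: DigitizedKM) -> IntervalCounts:
    """Allocate events and censorings per risk-table interval.

    Within an interval starting with ``n`` at risk, each digitized drop
    from S_prev to S contributes ``r * (1 - S/S_prev)`` events, where
    ``r`` is ``n`` minus events already allocated in the interval
    (censoring is treated as effective at the interval end for the event
    calculation). Events are rounded by largest remainder so that
    events + censored exactly equals the decline in the at-risk count.
    After the last risk-table entry only administrative censoring at the
    final follow-up time is assumed.
    """
    pts = list(km.points)
    rt = list(km.risk_table)
    if len(rt) < 2:
        # single risk entry: treat curve end as the closing boundary
        rt = rt + [(max(pts[-1][0], rt[0][0] + 1e-9), 0)]

    def surv_at(time: float) -> float:
        # step-function value of the digitized curve at `time` (left-continuous drops)
        s = 1.0
        for t, v in pts:
            if t <= time + 1e-12:
                s = v
            else:
                break
        return s

    intervals: list[dict] = []
    for i in range(len(rt) - 1):
        start, n_start = rt[i]
        end, n_end = rt[i + 1]
        if n_end > n_start:
            raise ReconstructionError(
                f"risk table increases on interval [{start}, {end}]"
            )
        leaving = n_start - n_end
        drops = [
            (t, s) for t, s in pts if start < t <= end + 1e-12
        ]
        s_prev = surv_at(start)
        real_events = []
        drop_times = []
        r = float(n_start)
        for t, s in drops:
            if s > s_prev + 1e-12:
                raise ReconstructionError(f"survival increases at t={t}")
            if s_prev <= 0:
                e = 0.0
            else:
                e = r * (1.0 - s / s_prev)
            real_events.append(e)
            drop_times.append(t)
            r = max(r - e, 0.0)
            s_prev = s
        total_real = float(np.sum(real_events)) if real_events else 0.0
        d = int(min(round(total_real), leaving))
        if total_real > leaving + 0.5 + 1e-9:
            raise ReconstructionError(
                f"interval [{start}, {end}]: curve implies {total_real:.1f} events "
                f"but only {leaving} patients leave the risk set"
            )
        counts = (
            _largest_remainder(np.asarray(real_events), d)
            if drop_times
            else np.zeros(0, dtype=int)
        )
        censored = leaving - d
        intervals.append(
            {
                "start": float(start),
                "end": float(end),
                "n_start": int(n_start),
                "event_times": tuple(drop_times),
                "event_counts": tuple(int(c) for c in counts),
                "censored": int(censored),
                "administrative": False,
            }
        )

    # beyond the last risk-table entry: administrative censoring only
    last_t, last_n = rt[-1]
    tail_drops = [(t, s) for t, s in pts if t > last_t + 1e-12]
    if last_n > 0:
        end = max((t for t, _ in tail_drops), default=last_t)
        s_prev = surv_at(last_t)
        real_events = []
        drop_times = []
        r = float(last_n)
        for t, s in tail_drops:
            e = r * (1.0 - s / s_prev) if s_prev > 0 else 0.0
            real_events.append(e)
            drop_times.append(t)
            r = max(r - e, 0.0)
            s_prev = s
        d = int(min(round(float(np.sum(real_events))) if real_events else 0, last_n))
        counts = (
            _largest_remainder(np.asarray(real_events), d)
            if drop_times
            else np.zeros(0, dtype=int)
        )
        intervals.append(
            {
                "start": float(last_t),
                "end": float(end),
                "n_start": int(last_n),
                "event_times": tuple(drop_times),
                "event_counts": tuple(int(c) for c in counts),
                "censored": int(last_n - d),
                "administrative": True,
            }
        )
    return IntervalCounts(tuple(intervals))


def expand_to_ipd(counts: IntervalCounts) -> PseudoIPD:
    """Expand interval counts into patient-level records.

    Events sit at their digitized drop times. The ``c`` censored
    records of an interval [a, b) are placed deterministically at
    ``a + k*(b-a)/(c+1)`` for k = 1..c, except in the final
    (administrative) interval where they sit at the closing time.
    """
    times: list[float] = []
    events: list[int] = []
    ivs = counts.intervals
    for idx, iv in enumerate(ivs):
        for t, d in zip(iv["event_times"], iv["event_counts"]):
            times.extend([t] * d)
            events.extend([1] * d)
        c = iv["censored"]
        if c > 0:
            a, b = iv["start"], iv["end"]
            if iv["administrative"] or b <= a:
                times.extend([max(b, a)] * c)
            else:
                step = (b - a) / (c + 1)
                times.extend([a + step * (k + 1) for k in range(c)])
            events.extend([0] * c)
    order = np.argsort(times, kind="stable")
    return PseudoIPD(
        tuple(float(times[i]) for i in order), tuple(events[i] for i in order)
    )


def km_from_ipd(ipd: PseudoIPD, risk_times=None) -> DigitizedKM:
    """Product-limit estimate of a pseudo-IPD sample.

    Returns a :class:`DigitizedKM` whose points are (0, 1) plus one
    point per distinct event time; the risk table is evaluated at
    ``risk_times`` (default: the distinct event times).
    """
    if len(ipd) == 0:
        raise ValueError("km_from_ipd requires at least one record")
    t = np.asarray(ipd.times)
    e = np.asarray(ipd.events)
    order = np.lexsort((1 - e, t))  # by time, events before censorings at ties
    t, e = t[order], e[order]
    n = len(t)
    points = [(0.0, 1.0)]
    s = 1.0
    i = 0
    at_risk = n
    while i < n:
        ti = t[i]
        d = 0
        c = 0
        while i < n and t[i] == ti:
            if e[i] == 1:
                d += 1
            else:
                c += 1
            i += 1
        if d > 0:
            s *= 1.0 - d / at_risk
            points.append((float(ti), float(s)))
        at_risk -= d + c
    if risk_times is None:
        risk_times = [tp for tp, _ in points[1:]] or [0.0]
    risk = [(float(rt), int(np.sum(t >= rt - 1e-12))) for rt in risk_times]
    if not risk or risk[0][0] > 0.0:
        risk = [(0.0, n)] + risk
    return DigitizedKM(tuple(points), tuple(risk))


def km_survival_function(ipd: PseudoIPD):
    """Return a step function t -> S_KM(t) for a pseudo-IPD sample."""
    km = km_from_ipd(ipd)
    times = np.array([t for t, _ in km.points])
    surv = np.array([s for _, s in km.points])

    def f(t):
        idx = np.searchsorted(times, np.asarray(t, dtype=float), side="right") - 1
        return surv[np.maximum(idx, 0)]

    return f
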