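"""Three-state cohort engine: trace construction and discounted accrual.

The model has three health states — progression-free (PFS), progressed
(PD), dead — and is evaluated as a partitioned-survival model: state
occupancy is read directly off the two fitted curves,

    pfs(t) = S_pfs(t),   dead(t) = 1 - S_os(t),
    pd(t)  = max(0, S_os(t) - S_pfs(t)),

on a grid of treatment cycles (default three weeks). Where the fitted
curves cross (S_pfs > S_os, which extrapolation can produce), PD is
clamped at zero and the clamp is counted. A per-cycle Markov transition
mode built from conditional cycle probabilities is available as a
cross-check; the two agree whenever the curves do not cross.

Accrual applies half-cycle correction (trapezoid average of adjacent
occupancies), discounts continuously at mid-cycle, and attaches one-off
values (e.g. end-of-life cost) to the per-cycle increment of the dead
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: days per cycle matching a three-weekly administration schedule
DEFAULT_CYCLE_DAYS = 21.0
DAYS_PER_YEAR = 365.25
MONTHS_PER_YEAR = 12.0

STATES = ("pfs", "pd", "dead")


@dataclass(frozen=True)
class ModelSettings:
    """Global cohort-model settings.

    ``cycle_length_days`` defaults to 21 (three weeks). ``horizon_years``
    is a cap; the trace also stops once cohort survival falls below
    ``survival_floor`` (lifetime horizon in practice).
    ``discount_rate_annual`` applies to both costs and health outcomes.
    """

    cycle_length_days: float = DEFAULT_CYCLE_DAYS
    horizon_years: float = 20.0
    discount_rate_annual: float = 0.03
    half_cycle_correction: bool = True
    survival_floor: float = 1e-3

    def __post_init__(self) -> None:
        if self.cycle_length_days <= 0:
            raise ValueError("cycle length must be positive")
        if not (0.0 <= self.discount_rate_annual < 1.0):
            raise ValueError("discount rate must lie in [0, 1)")
        if self.horizon_years <= 0:
            raise ValueError("horizon must be positive")

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR

    @property
    def cycle_months(self) -> float:
        return self.cycle_years * MONTHS_PER_YEAR


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy per cycle; row k is the start of cycle k."""

    times_months: np.ndarray
    pfs: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    clamp_count: int = 0

    def __post_init__(self) -> None:
        total = self.pfs + self.pd + self.dead
        if np.any(np.abs(total - 1.0) > 1e-9):
            raise ValueError("state occupancies must sum to 1 within 1e-9")
        if np.any(np.diff(self.dead) < -1e-12):
            raise ValueError("dead occupancy must be non-decreasing")

    @property
    def n_cycles(self) -> int:
        """Number of cycles (intervals); the arrays have n_cycles + 1 rows."""
        return len(self.times_months) - 1

    def membership(self, state: str) -> np.ndarray:
        return {"pfs": self.pfs, "pd": self.pd, "dead": self.dead}[state]

    def to_frame(self):
        import pandas as pd_mod

        return pd_mod.DataFrame(
            {
                "cycle": np.arange(len(self.times_months)),
                "time_months": self.times_months,
                "pfs": self.pfs,
                "pd": self.pd,
                "dead": self.dead,
            }
        )


def build_trace(pfs_curve, os_curve, settings: ModelSettings) -> CohortTrace:
    """Partitioned-survival trace from PFS and OS curves.

    Curves are any objects exposing ``survival(t_months)`` (a
    :class:`~survecon.survival.DistributionSpec` or
    :class:`~survecon.survival.HRAdjustedCurve`). The trace runs to the
    horizon or until overall survival drops below the survival floor,
    whichever is earlier, and always contains at least one full cycle.
    """
    u = settings.cycle_months
    horizon_months = settings.horizon_years * MONTHS_PER_YEAR
    if horizon_months < u:
        raise ValueError("horizon shorter than one cycle")
    n_max = int(np.ceil(horizon_months / u))
    times = np.arange(n_max + 1) * u
    s_os = np.asarray(os_curve.survival(times), dtype=float)
    # lifetime horizon: stop once the cohort is (numerically) extinct
    alive = np.nonzero(s_os >= settings.survival_floor)[0]
    last = int(alive[-1]) + 1 if len(alive) else 1
    last = max(min(last, n_max), 1)
    times = times[: last + 1]
    s_os = s_os[: last + 1]
    s_pfs = np.asarray(pfs_curve.survival(times), dtype=float)

    pd_raw = s_os - s_pfs
    clamp = int(np.sum(pd_raw < -1e-12))
    pd_state = np.maximum(pd_raw, 0.0)
    pfs_state = np.minimum(s_pfs, s_os)  # keep occupancies summing to 1 after clamping
    dead = 1.0 - s_os
    return CohortTrace(times, pfs_state, pd_state, dead, clamp_count=clamp)


def build_trace_markov(pfs_curve, os_curve, settings: ModelSettings) -> CohortTrace:
    """Per-cycle Markov alternative to :func:`build_trace`.

    Transition probabilities are conditional cycle probabilities from
    the same curves: PFS exit uses S_pfs, death uses S_os applied to
    both alive states. Agrees with the partitioned-survival trace when
    the curves do not cross (PFS exits split between PD and death so
    that total death matches S_os).
    """
    ps = build_trace(pfs_curve, os_curve, settings)  # reuse grid/stopping rule
    times = ps.times_months
    n = len(times)
    pfs = np.empty(n)
    pd_state = np.empty(n)
    dead = np.empty(n)
    pfs[0], pd_state[0], dead[0] = 1.0, 0.0, 0.0
    s_pfs = np.asarray(pfs_curve.survival(times), dtype=float)
    s_os = np.asarray(os_curve.survival(times), dtype=float)
    for k in range(n - 1):
        p_stay_pfs = s_pfs[k + 1] / s_pfs[k] if s_pfs[k] > 0 else 0.0
        p_surv = s_os[k + 1] / s_os[k] if s_os[k] > 0 else 0.0
        new_pfs = pfs[k] * min(p_stay_pfs, p_surv)
        alive = (pfs[k] + pd_state[k]) * p_surv
        pfs[k + 1] = new_pfs
        pd_state[k + 1] = max(alive - new_pfs, 0.0)
        dead[k + 1] = 1.0 - alive
    return CohortTrace(times, pfs, pd_state, dead, clamp_count=ps.clamp_count)


def discount_factor(rate_annual: float, t_years):
    """Continuous-time discount factor (1 + r)^(-t)."""
    t = np.asarray(t_years, dtype=float)
    if np.any(t < 0):
        raise ValueError("cannot discount negative times")
    out = (1.0 + rate_annual) ** (-t)
    return float(out) if np.isscalar(t_years) or t.ndim == 0 else out


def accrue(
    trace: CohortTrace,
    per_state_per_cycle: Mapping[str, np.ndarray | float],
    settings: ModelSettings,
    one_off_on_death: float = 0.0,
    entry_one_off: float = 0.0,
) -> float:
    """Discounted total of per-cycle state values over the trace.

    ``per_state_per_cycle`` maps state name to a scalar or an array of
    per-cycle values (length ``n_cycles``). With half-cycle correction
    the occupancy of cycle k is the average of the memberships at its
    two boundaries; discounting is evaluated at mid-cycle. One-off
    values attach to the death increment of each cycle
    (``one_off_on_death``) or to model entry, undiscounted
    (``entry_one_off``).
    """
    n = trace.n_cycles
    if n < 1:
        return float(entry_one_off)
    u_years = settings.cycle_years
    t_start_years = trace.times_months[:-1] / MONTHS_PER_YEAR
    df = discount_factor(settings.discount_rate_annual, t_start_years + u_years / 2.0)

    total = 0.0
    for state in STATES:
        if state not in per_state_per_cycle:
            continue
        vals = np.asarray(per_state_per_cycle[state], dtype=float)
        if vals.ndim == 0:
            vals = np.full(n, float(vals))
        if len(vals) != n:
            raise ValueError(
                f"value stream for {state!r} has length {len(vals)}, trace has {n} cycles"
            )
        m = trace.membership(state)
        occ = 0.5 * (m[:-1] + m[1:]) if settings.half_cycle_correction else m[:-1]
        total += float(np.sum(df * vals * occ))
    if one_off_on_death:
        death_inc = np.diff(trace.dead)
        total += float(one_off_on_death * np.sum(df * death_inc))
    total += float(entry_one_off)
    return total


def life_years(trace: CohortTrace, settings: ModelSettings) -> float:
    """Discounted life-years: accrual of one year-per-year while alive."""
    u = settings.cycle_years
    return accrue(trace, {"pfs": u, "pd": u}, settings)


def qalys(
    trace: CohortTrace,
    state_utilities: Mapping[str, float],
    settings: ModelSettings,
    ae_qaly_decrement: float = 0.0,
) -> float:
    """Discounted QALYs: utility-weighted life-years minus AE disutility.

    ``state_utilities`` maps 'pfs' and 'pd' to utilities in [0, 1]
    (values outside the range warn but are allowed, since adverse-event
    disutilities can push an effective utility below a state's
    baseline). ``ae_qaly_decrement`` is subtracted once at model entry.
    """
    import warnings

    for state, uval in state_utilities.items():
        if not (0.0 <= uval <= 1.0):
            warnings.warn(f"utility for {state!r} outside [0, 1]: {uval}")
    u = settings.cycle_years
    streams = {s: u * state_utilities.get(s, 0.0) for s in ("pfs", "pd")}
    return accrue(trace, streams, settings) - float(ae_qaly_decrement)
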