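"""Incremental analysis, NMB decision rules, threshold and subgroup runs.

The incremental cost-effectiveness ratio is reported as the raw ratio
dCost / dQALY without quadrant relabeling, so a strategy that is both
cheaper and less effective (south-west quadrant) prints a positive
ICER, and a costlier-but-less-effective one prints a negative ICER; the
``dominance`` flag carries the interpretation. Net monetary benefit
NMB = WTP * QALY - Cost provides the quadrant-free decision rule and
backs the acceptability curve and the price-threshold search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import optimize

from survecon.survival import HRAdjustedCurve


@dataclass(frozen=True)
class ArmResult:
    """Discounted totals of one evaluated strategy arm."""

    name: str
    cost: float
    life_years: float
    qalys: float
    trace: object | None = None


@dataclass(frozen=True)
class CEResult:
    """Pairwise incremental comparison of intervention vs comparator."""

    intervention: ArmResult
    comparator: ArmResult
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer_per_qaly: float | None
    icer_per_ly: float | None
    dominance: Literal["dominant", "dominated", "tradeoff", "equivalent"]

    def nmb(self, wtp: float) -> float:
        """Incremental net monetary benefit at the given WTP."""
        return net_monetary_benefit(self.delta_cost, self.delta_qaly, wtp)

    def preferred(self, wtp: float) -> str:
        return self.intervention.name if self.nmb(wtp) > 0 else self.comparator.name


@dataclass(frozen=True)
class SubgroupSpec:
    """A subgroup defined only by its PFS and OS hazard ratios."""

    name: str
    hr_pfs: float
    hr_os: float
    hr_pfs_ci: tuple[float, float] | None = None
    hr_os_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.hr_pfs <= 0 or self.hr_os <= 0:
            raise ValueError("hazard ratios must be positive")


def incremental_analysis(a: ArmResult, b: ArmResult) -> CEResult:
    """Incremental quantities of intervention ``a`` over comparator ``b``.

    ICERs are undefined (None) when the effect difference is zero; the
    ratio is otherwise reported sign-and-all.
    """
    dc = a.cost - b.cost
    dq = a.qalys - b.qalys
    dly = a.life_years - b.life_years
    icer_q = dc / dq if dq != 0 else None
    icer_ly = dc / dly if dly != 0 else None
    if dc == 0 and dq == 0:
        dom = "equivalent"
    elif dc <= 0 and dq >= 0:
        dom = "dominant"
    elif dc >= 0 and dq <= 0:
        dom = "dominated"
    else:
        dom = "tradeoff"
    return CEResult(a, b, dc, dq, dly, icer_q, icer_ly, dom)


def net_monetary_benefit(cost: float, qaly: float, wtp: float) -> float:
    """NMB = WTP * QALY - Cost. Works on totals or increments alike."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * qaly - cost


def price_threshold_search(
    model: Callable[[float], CEResult],
    wtp: float,
    bracket: tuple[float, float],
    tol: float = 1e-3,
) -> float:
    """Drug unit price at which the incremental NMB is zero.

    ``model`` maps a unit price to a :class:`CEResult` evaluated at
    that price; because total drug cost is linear in unit price the
    incremental NMB is monotone and bisection (Brent) applies. Raises
    if the NMB does not change sign over the bracket, reporting the end
    values.
    """

    def f(price: float) -> float:
        return model(price).nmb(wtp)

    lo, hi = bracket
    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return float(lo)
    if f_hi == 0.0:
        return float(hi)
    if math.copysign(1.0, f_lo) == math.copysign(1.0, f_hi):
        raise ValueError(
            f"incremental NMB does not change sign over [{lo}, {hi}]: "
            f"NMB({lo})={f_lo:.2f}, NMB({hi})={f_hi:.2f}"
        )
    return float(optimize.brentq(f, lo, hi, xtol=tol))


def run_subgroup(
    comparator_pfs,
    comparator_os,
    spec: SubgroupSpec,
    evaluate: Callable[[object, object, object, object], CEResult],
    hr_mode: str = "proportional_hazards",
) -> CEResult:
    """Evaluate a subgroup for which only hazard ratios are reported.

    The comparator keeps the base-case curves; the intervention curves
    are the comparator curves adjusted by the subgroup's PFS and OS
    hazard ratios. ``evaluate`` receives
    (intervention_pfs, intervention_os, comparator_pfs, comparator_os)
    and must return the full incremental result with all non-curve
    inputs inherited from the base case.
    """
    int_pfs = HRAdjustedCurve(comparator_pfs, spec.hr_pfs, hr_mode)
    int_os = HRAdjustedCurve(comparator_os, spec.hr_os, hr_mode)
    return evaluate(int_pfs, int_os, comparator_pfs, comparator_os)


def run_scenario(result, wtp_list: Sequence[float]):
    """Decision (or acceptance probability) at each WTP threshold.

    For a deterministic :class:`CEResult`: returns rows of
    (wtp, incremental NMB, preferred arm). For a PSA sample (anything
    with ``delta_cost``/``delta_qaly`` arrays): returns rows of
    (wtp, probability the intervention is cost-effective), delegating
    to the acceptability-curve logic.
    """
    wtps = list(wtp_list)
    if not wtps:
        raise ValueError("empty WTP list")
    if any(w < 0 for w in wtps):
        raise ValueError("WTP thresholds must be non-negative")
    if isinstance(result, CEResult):
        return [
            {"wtp": w, "incremental_nmb": result.nmb(w), "preferred": result.preferred(w)}
            for w in wtps
        ]
    from survecon.sensitivity import ceac

    curve = ceac(result, wtps)
    return [{"wtp": w, "probability_cost_effective": p} for w, p in curve]
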