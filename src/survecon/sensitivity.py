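"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way analysis re-evaluates the model at each parameter's low and
high bound (its 95% CI where available, else +/-25% of base) holding
everything else at base, and ranks parameters by the span of the
resulting ICERs. Probabilistic analysis draws all parameters jointly
and independently from role-specific distributions — gamma for costs,
beta for probabilities and utilities, normal for hazard ratios, BSA and
body weight (truncated positive by redraw) — with distribution
parameters matched by the method of moments, and summarizes the draws
as a scatter of incremental (effect, cost) pairs and an acceptability
curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from survecon.economics import CEResult

Role = Literal["cost", "probability", "utility", "hr", "bsa", "weight"]

#: roles drawn from a normal distribution, truncated at zero by redraw
_NORMAL_ROLES = ("hr", "bsa", "weight")

#: divisor converting a (low, high) range read as a 95% CI into an SE
DEFAULT_CI_DIVISOR = 2.0 * 1.959963984540054


@dataclass(frozen=True)
class ParameterDef:
    """One uncertain model input.

    ``low``/``high`` default to +/-25% of ``base`` when not given. The
    PSA distribution family follows ``role``; its moments are the base
    value and ``se = (high - low) / (2 * 1.96)`` (range read as a 95%
    interval).
    """

    name: str
    role: Role
    base: float
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        lo = self.base * 0.75 if self.low is None else self.low
        hi = self.base * 1.25 if self.high is None else self.high
        if lo > hi:
            lo, hi = hi, lo
        if self.role in ("probability", "utility"):
            lo, hi = max(lo, 0.0), min(hi, 1.0)
        if not (lo <= self.base <= hi):
            raise ValueError(
                f"{self.name}: base {self.base} outside [{lo}, {hi}]"
            )
        object.__setattr__(self, "low", float(lo))
        object.__setattr__(self, "high", float(hi))

    @property
    def se(self) -> float:
        return (self.high - self.low) / DEFAULT_CI_DIVISOR


@dataclass(frozen=True)
class PSASample:
    """Draws and per-draw model outputs of a probabilistic analysis."""

    draws: pd.DataFrame  # one column per parameter
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    cost_a: np.ndarray
    cost_b: np.ndarray
    qaly_a: np.ndarray
    qaly_b: np.ndarray
    seed: int

    def __len__(self) -> int:
        return len(self.delta_cost)

    def scatter_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"delta_qaly": self.delta_qaly, "delta_cost": self.delta_cost}
        )


def moment_match(role: Role, mean: float, se: float) -> tuple[float, ...]:
    """Distribution parameters reproducing (mean, se) for a role.

    cost -> gamma(shape, scale); probability/utility -> beta(alpha,
    beta); hr/bsa/weight -> normal(mean, se). Beta matching requires
    se^2 < mean * (1 - mean).
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if role == "cost":
        return (mean**2 / se**2, se**2 / mean)
    if role in ("probability", "utility"):
        if not (0.0 < mean < 1.0):
            raise ValueError("beta moment matching requires mean in (0, 1)")
        nu = mean * (1.0 - mean) / se**2 - 1.0
        if nu <= 0:
            raise ValueError(
                f"beta infeasible: se^2={se**2:.4g} >= mean(1-mean)={mean*(1-mean):.4g}"
            )
        return (mean * nu, (1.0 - mean) * nu)
    if role in _NORMAL_ROLES:
        return (mean, se)
    raise ValueError(f"unknown role {role!r}")


def _draw(rng: np.random.Generator, p: ParameterDef, size: int) -> np.ndarray:
    if p.se == 0.0:
        return np.full(size, p.base)
    params = moment_match(p.role, p.base, p.se)
    if p.role == "cost":
        return rng.gamma(params[0], params[1], size)
    if p.role in ("probability", "utility"):
        return rng.beta(params[0], params[1], size)
    out = rng.normal(params[0], params[1], size)
    bad = out <= 0
    while np.any(bad):  # truncate positive by redraw
        out[bad] = rng.normal(params[0], params[1], int(bad.sum()))
        bad = out <= 0
    return out


def owsa(
    model: Callable[[Mapping[str, float]], CEResult],
    parameters: Sequence[ParameterDef],
    wtp: float | None = None,
) -> pd.DataFrame:
    """One-way sensitivity analysis (tornado table).

    ``model`` re-evaluates the full pipeline under a parameter-override
    mapping; an empty mapping gives the base case. Each row reports the
    ICER at the parameter's low and high bound and the span between
    them; rows are sorted descending by span. If the effect difference
    changes sign across a bound the ICER there is undefined and the
    span falls back to the incremental-NMB span at ``wtp`` (flagged in
    the ``span_metric`` column).
    """
    base = model({})
    rows = []
    for p in parameters:
        res_lo = model({p.name: p.low})
        res_hi = model({p.name: p.high})
        icer_lo, icer_hi = res_lo.icer_per_qaly, res_hi.icer_per_qaly
        crossed = (
            icer_lo is None
            or icer_hi is None
            or np.sign(res_lo.delta_qaly) != np.sign(res_hi.delta_qaly)
        )
        if crossed:
            if wtp is None:
                raise ValueError(
                    f"parameter {p.name!r} crosses delta-effect 0; pass a WTP "
                    "so the span can fall back to NMB"
                )
            span = abs(res_hi.nmb(wtp) - res_lo.nmb(wtp))
            metric = "nmb"
        else:
            span = abs(icer_hi - icer_lo)
            metric = "icer"
        rows.append(
            {
                "parameter": p.name,
                "low": p.low,
                "high": p.high,
                "icer_low": icer_lo,
                "icer_high": icer_hi,
                "span": span,
                "span_metric": metric,
            }
        )
    df = pd.DataFrame(rows).sort_values("span", ascending=False, kind="stable")
    df.attrs["base_icer"] = base.icer_per_qaly
    return df.reset_index(drop=True)


def run_psa(
    model: Callable[[Mapping[str, float]], CEResult],
    parameters: Sequence[ParameterDef],
    iterations: int = 10_000,
    seed: int = 0,
) -> PSASample:
    """Monte-Carlo probabilistic sensitivity analysis.

    All parameters vary simultaneously and independently; the model is
    re-evaluated per draw. Output is bit-reproducible for a given seed.
    Infeasible distributions raise before any draw.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    for p in parameters:  # validate everything up front
        if p.se > 0:
            moment_match(p.role, p.base, p.se)
    rng = np.random.default_rng(seed)
    draws = pd.DataFrame({p.name: _draw(rng, p, iterations) for p in parameters})
    dc = np.empty(iterations)
    dq = np.empty(iterations)
    ca = np.empty(iterations)
    cb = np.empty(iterations)
    qa = np.empty(iterations)
    qb = np.empty(iterations)
    for i in range(iterations):
        res = model(draws.iloc[i].to_dict())
        dc[i], dq[i] = res.delta_cost, res.delta_qaly
        ca[i], cb[i] = res.intervention.cost, res.comparator.cost
        qa[i], qb[i] = res.intervention.qalys, res.comparator.qalys
    return PSASample(draws, dc, dq, ca, cb, qa, qb, seed)


def ceac(sample: PSASample, wtp_grid: Sequence[float]) -> list[tuple[float, float]]:
    """Cost-effectiveness acceptability curve.

    At each WTP, the fraction of PSA draws in which the intervention
    has positive incremental net monetary benefit.
    """
    wtps = list(wtp_grid)
    if not wtps:
        raise ValueError("empty WTP grid")
    if len(sample) == 0:
        raise ValueError("empty PSA sample")
    out = []
    for w in wtps:
        nmb = w * sample.delta_qaly - sample.delta_cost
        out.append((float(w), float(np.mean(nmb > 0))))
    return out


def ceac_frame(sample: PSASample, wtp_grid: Sequence[float]) -> pd.DataFrame:
    return pd.DataFrame(ceac(sample, wtp_grid), columns=["wtp", "probability_cost_effective"])
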