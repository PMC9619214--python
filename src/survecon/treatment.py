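"""Regimens, unit costs, adverse events, utilities -> per-cycle streams.

Turns the clinical and economic inputs of one strategy arm into the
per-state per-cycle value streams the cohort engine accrues:

* drug acquisition per cycle, with per-m2 / per-kg dose resolution
  (body surface area and weight are locale-level assumptions), fixed
  maximum cycle counts (e.g. four platinum cycles) and maintenance
  components that continue until progression;
* adverse events restricted to grade >=3 toxicities whose incidence
  differs by more than five percentage points between arms, applied as
  an expected one-off cost and QALY decrement at model entry;
* post-progression care as a mixture of subsequent active therapy and
  best supportive care;
* one-off costs (mutation testing at entry, end-of-life care attached
  to the death increment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from survecon.engine import CohortTrace, ModelSettings, accrue, build_trace, life_years, qalys


class ConfigurationError(ValueError):
    """An arm or locale definition is incomplete or inconsistent."""


@dataclass(frozen=True)
class RegimenComponent:
    """One drug within a regimen.

    ``dose_rule`` resolves the administered dose: ``flat`` uses
    ``dose`` in mg as-is, ``per_m2`` multiplies by BSA, ``per_kg`` by
    body weight. ``schedule`` is ``daily`` (one administration per day
    of the cycle) or ``per_cycle`` (one administration per cycle).
    ``max_cycles`` caps the number of cycles the component is given
    (None = until progression). ``infused`` components incur the
    locale's infusion cost per administration.
    """

    drug: str
    dose: float
    dose_rule: Literal["flat", "per_m2", "per_kg"] = "flat"
    schedule: Literal["daily", "per_cycle"] = "per_cycle"
    max_cycles: int | None = None
    infused: bool = False

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if self.max_cycles is not None and self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")


@dataclass(frozen=True)
class Regimen:
    name: str
    components: tuple[RegimenComponent, ...]


@dataclass(frozen=True)
class LocaleEconomics:
    """Locale-level unit prices and cost assumptions (2021 USD).

    Drug prices are per mg. ``bsa`` (m^2) and ``weight`` (kg) resolve
    per-m^2 / per-kg doses; reference cohort values are 1.79 m^2 / 70 kg
    (US) and 1.72 m^2 / 65 kg (China).
    """

    name: str
    drug_prices_per_mg: Mapping[str, float]
    bsa: float
    weight: float
    egfr_testing_cost: float = 0.0
    follow_up_cost_per_cycle: float = 0.0
    bsc_cost_per_cycle: float = 0.0
    end_of_life_cost: float = 0.0
    radiotherapy_cost: float = 0.0
    infusion_cost_per_administration: float = 0.0
    discount_rate_annual: float = 0.03
    wtp_per_qaly: float = 150_000.0

    def __post_init__(self) -> None:
        costs = [
            self.egfr_testing_cost, self.follow_up_cost_per_cycle,
            self.bsc_cost_per_cycle, self.end_of_life_cost,
            self.radiotherapy_cost, self.infusion_cost_per_administration,
            *self.drug_prices_per_mg.values(),
        ]
        if any(c < 0 for c in costs):
            raise ConfigurationError("costs must be non-negative")
        if self.bsa <= 0 or self.weight <= 0:
            raise ConfigurationError("BSA and weight must be positive")


@dataclass(frozen=True)
class AdverseEventEntry:
    """One grade >=3 adverse event with per-arm incidences.

    ``duration_years`` is how long the disutility applies; the cost is
    a one-off management cost.
    """

    name: str
    incidence_a: float
    incidence_b: float
    cost: float
    disutility: float
    duration_years: float

    def __post_init__(self) -> None:
        for inc in (self.incidence_a, self.incidence_b):
            if not (0.0 <= inc <= 1.0):
                raise ValueError(f"incidence out of [0,1] for AE {self.name!r}")
        if self.duration_years < 0:
            raise ValueError(f"negative AE duration for {self.name!r}")


@dataclass(frozen=True)
class PostProgressionPolicy:
    """Care mix after progression.

    A fraction of progressed patients receives subsequent active
    therapy (costed per cycle); the remainder receives best supportive
    care. ``discontinuation_fraction`` is the share of the arm that
    stops the assigned drug for toxicity while still progression-free;
    their drug-acquisition cost is removed from the second cycle on.
    """

    subsequent_fraction: float
    subsequent_cost_per_cycle: float
    discontinuation_fraction: float = 0.0

    def __post_init__(self) -> None:
        for f in (self.subsequent_fraction, self.discontinuation_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if self.subsequent_cost_per_cycle < 0:
            raise ValueError("subsequent-therapy cost must be non-negative")


@dataclass(frozen=True)
class ArmSpec:
    """Everything needed to evaluate one strategy arm."""

    name: str
    pfs_curve: object  # anything with .survival(t_months)
    os_curve: object
    regimen: Regimen
    post_progression: PostProgressionPolicy
    utility_pfs: float
    utility_pd: float
    adverse_events: tuple[AdverseEventEntry, ...]
    ae_arm: Literal["a", "b"]
    locale: LocaleEconomics
    radiotherapy_fraction: float = 0.0


@dataclass(frozen=True)
class ValueStreams:
    """Per-cycle cost streams plus one-offs, ready for accrual."""

    cost_pfs: np.ndarray
    cost_pd: np.ndarray
    utility_pfs: float
    utility_pd: float
    entry_cost: float
    entry_qaly_decrement: float
    end_of_life_cost: float


def _resolve_dose(component: RegimenComponent, locale: LocaleEconomics) -> float:
    if component.dose_rule == "flat":
        return component.dose
    if component.dose_rule == "per_m2":
        return component.dose * locale.bsa
    if component.dose_rule == "per_kg":
        return component.dose * locale.weight
    raise ConfigurationError(f"unknown dose rule {component.dose_rule!r}")


def regimen_cycle_cost(
    regimen: Regimen,
    cycle_index: int,
    locale: LocaleEconomics,
    cycle_days: float = 21.0,
) -> float:
    """Drug-acquisition plus administration cost of one cycle.

    ``cycle_index`` counts from 0; a component with ``max_cycles = m``
    contributes only for cycles 0..m-1. Daily components are
    administered once per day of the cycle.
    """
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    total = 0.0
    for comp in regimen.components:
        if comp.max_cycles is not None and cycle_index >= comp.max_cycles:
            continue
        if comp.drug not in locale.drug_prices_per_mg:
            raise ConfigurationError(
                f"no unit price for drug {comp.drug!r} in locale {locale.name!r}"
            )
        n_admin = cycle_days if comp.schedule == "daily" else 1.0
        dose = _resolve_dose(comp, locale)
        total += dose * n_admin * locale.drug_prices_per_mg[comp.drug]
        if comp.infused:
            total += n_admin * locale.infusion_cost_per_administration
    return total


def filter_adverse_events(
    table: Sequence[AdverseEventEntry], threshold: float = 0.05
) -> list[AdverseEventEntry]:
    """Keep AEs whose between-arm incidence differs by more than ``threshold``."""
    return [ae for ae in table if abs(ae.incidence_a - ae.incidence_b) > threshold]


def ae_burden(
    included: Sequence[AdverseEventEntry], arm: Literal["a", "b"]
) -> tuple[float, float]:
    """Expected one-off AE cost and QALY decrement for one arm.

    Cost = sum incidence * management cost; decrement
    = sum incidence * disutility * duration, both applied once at
    model entry.
    """
    cost = 0.0
    decrement = 0.0
    for ae in included:
        inc = ae.incidence_a if arm == "a" else ae.incidence_b
        cost += inc * ae.cost
        decrement += inc * ae.disutility * ae.duration_years
    return cost, decrement


def build_value_streams(
    arm: ArmSpec, n_cycles: int, settings: ModelSettings
) -> ValueStreams:
    """Assemble the per-cycle cost/utility streams of one arm.

    PFS: drug acquisition (scaled by 1 - discontinuation fraction from
    the second cycle onward), follow-up, and any infusion costs; a
    radiotherapy one-off applies to the treated fraction at entry. PD:
    the subsequent-therapy / BSC mixture. Entry one-offs: mutation
    testing plus the expected AE burden. End-of-life cost rides on the
    death increment.
    """
    loc = arm.locale
    pp = arm.post_progression
    keep = 1.0 - pp.discontinuation_fraction
    drug = np.array(
        [
            regimen_cycle_cost(arm.regimen, k, loc, settings.cycle_length_days)
            for k in range(n_cycles)
        ]
    )
    drug[1:] *= keep
    cost_pfs = drug + loc.follow_up_cost_per_cycle
    pd_per_cycle = (
        pp.subsequent_fraction * pp.subsequent_cost_per_cycle
        + (1.0 - pp.subsequent_fraction) * loc.bsc_cost_per_cycle
    )
    cost_pd = np.full(n_cycles, pd_per_cycle)
    ae_cost, ae_decrement = ae_burden(arm.adverse_events, arm.ae_arm)
    entry = loc.egfr_testing_cost + ae_cost + arm.radiotherapy_fraction * loc.radiotherapy_cost
    return ValueStreams(
        cost_pfs=cost_pfs,
        cost_pd=cost_pd,
        utility_pfs=arm.utility_pfs,
        utility_pd=arm.utility_pd,
        entry_cost=entry,
        entry_qaly_decrement=ae_decrement,
        end_of_life_cost=loc.end_of_life_cost,
    )


def evaluate_arm(arm: ArmSpec, settings: ModelSettings):
    """Run one arm through the engine; returns an ArmResult.

    Builds the partitioned-survival trace from the arm's curves,
    assembles value streams, and accrues discounted cost, life-years
    and QALYs.
    """
    from survecon.economics import ArmResult

    trace = build_trace(arm.pfs_curve, arm.os_curve, settings)
    vs = build_value_streams(arm, trace.n_cycles, settings)
    cost = accrue(
        trace,
        {"pfs": vs.cost_pfs, "pd": vs.cost_pd},
        settings,
        one_off_on_death=vs.end_of_life_cost,
        entry_one_off=vs.entry_cost,
    )
    ly = life_years(trace, settings)
    q = qalys(
        trace,
        {"pfs": vs.utility_pfs, "pd": vs.utility_pd},
        settings,
        ae_qaly_decrement=vs.entry_qaly_decrement,
    )
    return ArmResult(name=arm.name, cost=cost, life_years=ly, qalys=q, trace=trace)
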