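"""Synthetic trial fixtures shaped like a two-arm second-line NSCLC RCT.

Generates everything the pipeline consumes without any download: true
patient-level event data from known parametric distributions, a
"digitized" version of their Kaplan-Meier curves (step function sampled
on a reading grid, survival rounded to plot-reading precision) with
numbers-at-risk tables, and a complete locale configuration.

The default trial shape anchors the published second-line trial the
package models: intervention (osimertinib) vs platinum-pemetrexed,
median PFS 10.1 vs 4.4 months, median OS 26.8 vs 22.5 months,
log-logistic intervention curves and Weibull comparator curves, 279 vs
140 patients, administrative censoring at the data cutoff plus a small
random-censoring rate. Unit costs, utilities and the adverse-event
table in the emitted configs are synthetic stand-ins on realistic
scales, not published values; they are labeled as such in the emitted
files and are fully config-overridable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from survecon.reconstruct import DigitizedKM, PseudoIPD, km_from_ipd
from survecon.survival import DistributionSpec

ARM_INTERVENTION = "osimertinib"
ARM_COMPARATOR = "platinum_pemetrexed"
ENDPOINTS = ("pfs", "os")


@dataclass(frozen=True)
class ArmSimSpec:
    """True distributions and size of one simulated arm."""

    n: int
    pfs: DistributionSpec
    os: DistributionSpec

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("arm size must be >= 1")


@dataclass(frozen=True)
class TrialSimSpec:
    """A two-arm trial simulation: truth, censoring and reading grids."""

    arms: dict[str, ArmSimSpec]
    admin_cutoff_months: dict[str, float]  # per endpoint
    random_censor_rate: float = 0.005  # events per month
    risk_grid_step: float = 3.0
    digitize_grid_step: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.admin_cutoff_months.values()):
            raise ValueError("administrative cutoff must be positive")
        if self.random_censor_rate < 0:
            raise ValueError("censor rate must be non-negative")


def _sample_event_times(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draws from a survival distribution."""
    p = spec.params
    if spec.family == "exponential":
        return rng.exponential(1.0 / p[0], n)
    if spec.family == "weibull":
        # S = exp(-lam t^gamma): t = (E / lam)^(1/gamma), E ~ Exp(1)
        return (rng.exponential(1.0, n) / p[0]) ** (1.0 / p[1])
    if spec.family == "loglogistic":
        u = rng.uniform(0.0, 1.0, n)
        return p[0] * (u / (1.0 - u)) ** (1.0 / p[1])
    return rng.lognormal(p[0], p[1], n)


def simulate_arm(
    spec: DistributionSpec,
    n: int,
    admin_cutoff: float,
    censor_rate: float,
    rng: np.random.Generator,
) -> PseudoIPD:
    """Simulate one endpoint of one arm as patient-level records.

    Event times are drawn from ``spec``; each patient's censoring time
    is the minimum of the administrative cutoff and an exponential
    random-censoring draw; the record is (min(event, censor),
    event <= censor).
    """
    t_event = _sample_event_times(spec, n, rng)
    if censor_rate > 0:
        t_rand = rng.exponential(1.0 / censor_rate, n)
    else:
        t_rand = np.full(n, np.inf)
    t_cens = np.minimum(t_rand, admin_cutoff)
    observed = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    order = np.argsort(observed, kind="stable")
    return PseudoIPD(tuple(float(v) for v in observed[order]), tuple(int(v) for v in event[order]))


def digitize(
    ipd: PseudoIPD,
    curve_grid: np.ndarray,
    risk_grid: np.ndarray,
    round_decimals: int | None = 3,
) -> DigitizedKM:
    """Read a KM curve the way a graph digitizer would.

    The product-limit step function is sampled at ``curve_grid`` and
    survival is rounded to ``round_decimals`` (default 3, mimicking
    plot-reading precision; pass None for exact values). The risk table
    holds the exact number still under observation at each risk-grid
    time.
    """
    from survecon.reconstruct import km_survival_function

    sf = km_survival_function(ipd)
    grid = np.asarray(curve_grid, dtype=float)
    if grid.size == 0 or grid[0] != 0.0:
        grid = np.concatenate([[0.0], grid])
    surv = np.asarray(sf(grid), dtype=float)
    if round_decimals is not None:
        surv = np.round(surv, round_decimals)
    t_obs = np.asarray(ipd.times)
    risk = tuple(
        (float(rt), int(np.sum(t_obs >= rt - 1e-12))) for rt in np.asarray(risk_grid, dtype=float)
    )
    if not risk or risk[0][0] > 0:
        risk = ((0.0, len(ipd)),) + risk
    points = tuple((float(t), float(s)) for t, s in zip(grid, surv))
    return DigitizedKM(points, risk)


def default_trial_spec(seed: int = 0) -> TrialSimSpec:
    """The anchored two-arm trial shape (ITT population)."""
    log2 = float(np.log(2.0))
    return TrialSimSpec(
        arms={
            ARM_INTERVENTION: ArmSimSpec(
                n=279,
                pfs=DistributionSpec("loglogistic", (10.1, 1.8)),
                os=DistributionSpec("loglogistic", (26.8, 2.1)),
            ),
            ARM_COMPARATOR: ArmSimSpec(
                n=140,
                pfs=DistributionSpec("weibull", (log2 / 4.4**1.25, 1.25)),
                os=DistributionSpec("weibull", (log2 / 22.5**1.4, 1.4)),
            ),
        },
        admin_cutoff_months={"pfs": 27.0, "os": 48.0},
        random_censor_rate=0.005,
        risk_grid_step=3.0,
        digitize_grid_step=0.25,
        seed=seed,
    )


#: Subgroup hazard ratios (intervention vs comparator) from the trial's
#: forest plots; the CNS row drives the CNS-metastases population.
SUBGROUP_HRS: dict[str, dict[str, float]] = {
    "cns": {"hr_pfs": 0.32, "hr_os": 1.19},
    "no_cns": {"hr_pfs": 0.40, "hr_os": 0.75},
    "asian": {"hr_pfs": 0.32, "hr_os": 0.84},
    "non_asian": {"hr_pfs": 0.48, "hr_os": 0.94},
    "male": {"hr_pfs": 0.43, "hr_os": 1.11},
    "female": {"hr_pfs": 0.34, "hr_os": 0.77},
    "exon19_deletion": {"hr_pfs": 0.34, "hr_os": 0.88},
    "l858r": {"hr_pfs": 0.46, "hr_os": 0.96},
    "prior_tki_ge_6mo": {"hr_pfs": 0.39, "hr_os": 0.87},
    "smoker": {"hr_pfs": 0.40, "hr_os": 0.87},
    "never_smoker": {"hr_pfs": 0.36, "hr_os": 0.87},
}


def _locale_block(locale: str) -> dict:
    """Locale economics: published drug prices and cohort anthropometrics;
    all other unit costs are synthetic stand-ins on realistic scales."""
    if locale == "us":
        return {
            "bsa": 1.79,
            "weight": 70.0,
            "drug_prices_per_mg": {"osimertinib": 6.62, "pemetrexed": 0.54, "cisplatin": 0.19},
            "egfr_testing_cost": 300.0,
            "follow_up_cost_per_cycle": 320.0,
            "bsc_cost_per_cycle": 1500.0,
            "end_of_life_cost": 10000.0,
            "radiotherapy_cost": 9000.0,
            "infusion_cost_per_administration": 150.0,
        }
    if locale == "china":
        return {
            "bsa": 1.72,
            "weight": 65.0,
            "drug_prices_per_mg": {"osimertinib": 0.36, "pemetrexed": 0.10, "cisplatin": 0.03},
            "egfr_testing_cost": 200.0,
            "follow_up_cost_per_cycle": 60.0,
            "bsc_cost_per_cycle": 250.0,
            "end_of_life_cost": 1800.0,
            "radiotherapy_cost": 1200.0,
            "infusion_cost_per_administration": 15.0,
        }
    raise ValueError(f"unknown locale {locale!r}; expected 'us' or 'china'")


def _ae_block(locale: str) -> list[dict]:
    """Grade >=3 AE table (synthetic stand-in; incidences per arm)."""
    us = locale == "us"
    scale = 1.0 if us else 0.12
    return [
        {"name": "neutropenia", "incidence_intervention": 0.02, "incidence_comparator": 0.12,
         "cost": round(16000 * scale, 2), "disutility": 0.20, "duration_years": 0.055},
        {"name": "anaemia", "incidence_intervention": 0.01, "incidence_comparator": 0.12,
         "cost": round(12000 * scale, 2), "disutility": 0.12, "duration_years": 0.082},
        {"name": "thrombocytopenia", "incidence_intervention": 0.01, "incidence_comparator": 0.07,
         "cost": round(15000 * scale, 2), "disutility": 0.11, "duration_years": 0.055},
        {"name": "diarrhoea", "incidence_intervention": 0.02, "incidence_comparator": 0.01,
         "cost": round(5000 * scale, 2), "disutility": 0.10, "duration_years": 0.03},
        {"name": "fatigue", "incidence_intervention": 0.01, "incidence_comparator": 0.04,
         "cost": round(4000 * scale, 2), "disutility": 0.12, "duration_years": 0.06},
    ]


def _base_config(locale: str, population: str) -> dict:
    us = locale == "us"
    cfg = {
        "locale": locale,
        "population": population,
        "settings": {
            "cycle_length_days": 21.0,
            "horizon_years": 20.0,
            "discount_rate_annual": 0.03 if us else 0.05,
            "half_cycle_correction": True,
        },
        "wtp_per_qaly": 150000.0 if us else 37489.0,
        "wtp_scenarios": [100000.0, 150000.0] if us else [19003.0, 37489.0, 85176.0],
        "selection_criterion": "aic",
        "hr_mode": "proportional_hazards",
        "economics": _locale_block(locale),
        "utilities": {"pfs": 0.804, "pd": 0.321} if us else {"pfs": 0.80, "pd": 0.58},
        "adverse_events": _ae_block(locale),
        "arms": {
            ARM_INTERVENTION: {
                "role": "intervention",
                "regimen": [
                    {"drug": "osimertinib", "dose": 80.0, "dose_rule": "flat", "schedule": "daily"}
                ],
                "discontinuation_fraction": 0.07,
                "subsequent_fraction": 0.53,
                "subsequent_cost_per_cycle": 2500.0 if us else 200.0,
            },
            ARM_COMPARATOR: {
                "role": "comparator",
                "regimen": [
                    {"drug": "cisplatin", "dose": 75.0, "dose_rule": "per_m2",
                     "schedule": "per_cycle", "max_cycles": 4, "infused": True},
                    {"drug": "pemetrexed", "dose": 500.0, "dose_rule": "per_m2",
                     "schedule": "per_cycle", "infused": True},
                ],
                "discontinuation_fraction": 0.10,
                "subsequent_fraction": 0.81,
                "subsequent_cost_per_cycle": 9000.0 if us else 450.0,
            },
        },
        "subgroups": {name: dict(hrs) for name, hrs in SUBGROUP_HRS.items()},
        "psa": {"iterations": 10000, "seed": 2021},
    }
    if population == "cns":
        cfg["population_hrs"] = dict(SUBGROUP_HRS["cns"])
    return cfg


@dataclass(frozen=True)
class FixtureStudy:
    """A complete synthetic study: curves, truth and configuration."""

    locale: str
    population: str
    seed: int
    trial: TrialSimSpec
    truth_ipd: dict[tuple[str, str], PseudoIPD]
    digitized: dict[tuple[str, str], DigitizedKM]
    config: dict

    def write(self, directory: str | Path) -> Path:
        """Emit curve/risk CSVs and the YAML config into ``directory``.

        Returns the path of the written config file. The config gains
        ``curves`` entries pointing at the CSVs.
        """
        import yaml

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cfg = copy.deepcopy(self.config)
        for (arm, endpoint), km in sorted(self.digitized.items()):
            curve = f"{arm}_{endpoint}_curve.csv"
            risk = f"{arm}_{endpoint}_risk.csv"
            km.to_csv(directory / curve, directory / risk)
            cfg["arms"][arm].setdefault("curves", {})[endpoint] = {
                "curve_csv": curve,
                "risk_csv": risk,
            }
        truth = {
            f"{arm}_{endpoint}": {
                "family": self.trial.arms[arm].pfs.family if endpoint == "pfs" else self.trial.arms[arm].os.family,
                "params": list(
                    (self.trial.arms[arm].pfs if endpoint == "pfs" else self.trial.arms[arm].os).params
                ),
            }
            for (arm, endpoint) in sorted(self.digitized.keys())
        }
        header = (
            "# Synthetic fixture emitted by survecon make-fixtures.\n"
            "# Drug prices, dosing, discount rates and WTP thresholds follow the\n"
            "# modelled setting; all other unit costs, utilities and AE values are\n"
            "# synthetic stand-ins, not published values.\n"
        )
        cfg_path = directory / "config.yaml"
        with open(cfg_path, "w") as fh:
            fh.write(header)
            yaml.safe_dump(cfg, fh, sort_keys=False)
        with open(directory / "truth.yaml", "w") as fh:
            fh.write("# True generating distributions of the synthetic trial.\n")
            yaml.safe_dump({"seed": self.seed, "distributions": truth}, fh, sort_keys=False)
        return cfg_path


def make_fixture_study(locale: str, population: str = "itt", seed: int = 0) -> FixtureStudy:
    """Build a complete synthetic study bundle for one locale/population.

    For the CNS-metastases population no intervention curves are
    simulated: the configuration instead carries the subgroup hazard
    ratios, and the comparator overall-survival curve is shared with
    the ITT population — mirroring the assumption that comparator OS in
    the CNS subgroup equals comparator OS in the full population.
    """
    locale = locale.lower()
    population = population.lower()
    if population not in ("itt", "cns"):
        raise ValueError(f"unknown population {population!r}; expected 'itt' or 'cns'")
    trial = default_trial_spec(seed)
    rng = np.random.default_rng(seed)
    truth_ipd: dict[tuple[str, str], PseudoIPD] = {}
    digitized: dict[tuple[str, str], DigitizedKM] = {}
    need_arms = (
        (ARM_INTERVENTION, ARM_COMPARATOR) if population == "itt" else (ARM_COMPARATOR,)
    )
    for arm in (ARM_INTERVENTION, ARM_COMPARATOR):
        # draw both arms in a fixed order so ITT and CNS share the
        # comparator data stream for a given seed
        for endpoint in ENDPOINTS:
            spec = getattr(trial.arms[arm], endpoint)
            cutoff = trial.admin_cutoff_months[endpoint]
            ipd = simulate_arm(
                spec, trial.arms[arm].n, cutoff, trial.random_censor_rate, rng
            )
            if arm not in need_arms:
                continue
            grid = np.arange(0.0, cutoff + 1e-9, trial.digitize_grid_step)
            risk_grid = np.arange(0.0, cutoff + 1e-9, trial.risk_grid_step)
            truth_ipd[(arm, endpoint)] = ipd
            digitized[(arm, endpoint)] = digitize(ipd, grid, risk_grid)
    config = _base_config(locale, population)
    return FixtureStudy(
        locale=locale,
        population=population,
        seed=seed,
        trial=trial,
        truth_ipd=truth_ipd,
        digitized=digitized,
        config=config,
    )
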