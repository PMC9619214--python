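"""Run configuration, validation, and the end-to-end pipeline.

A run is declared in one YAML file (plus curve/risk CSVs it points at).
Validation is strict — unknown keys are errors — and collects *all*
problems before raising, each naming the offending key. The pipeline
composes the stages: reconstruct pseudo-IPD from digitized curves (or
take pre-fitted parameters), fit and select parametric distributions,
build the cohort trace, accrue costs and outcomes, and run the
incremental analysis; sensitivity machinery re-evaluates the same model
under parameter overrides.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from survecon.economics import (
    ArmResult,
    CEResult,
    SubgroupSpec,
    incremental_analysis,
)
from survecon.engine import ModelSettings
from survecon.reconstruct import (
    DigitizedKM,
    expand_to_ipd,
    reconstruct_interval_counts,
)
from survecon.sensitivity import ParameterDef
from survecon.survival import (
    FAMILIES,
    DistributionSpec,
    HRAdjustedCurve,
    SurvivalFit,
    fit_all_families,
    select_distribution,
)
from survecon.treatment import (
    AdverseEventEntry,
    ArmSpec,
    LocaleEconomics,
    PostProgressionPolicy,
    Regimen,
    RegimenComponent,
    ae_burden,
    evaluate_arm,
    filter_adverse_events,
)


class ConfigError(ValueError):
    """Invalid run configuration; message lists every offending key."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))


_TOP_KEYS = {
    "locale", "population", "settings", "wtp_per_qaly", "wtp_scenarios",
    "selection_criterion", "hr_mode", "economics", "utilities",
    "adverse_events", "arms", "subgroups", "population_hrs", "psa",
}
_SETTINGS_KEYS = {"cycle_length_days", "horizon_years", "discount_rate_annual", "half_cycle_correction"}
_ECON_KEYS = {
    "bsa", "weight", "drug_prices_per_mg", "egfr_testing_cost",
    "follow_up_cost_per_cycle", "bsc_cost_per_cycle", "end_of_life_cost",
    "radiotherapy_cost", "infusion_cost_per_administration",
}
_ARM_KEYS = {
    "role", "regimen", "curves", "fitted", "discontinuation_fraction",
    "subsequent_fraction", "subsequent_cost_per_cycle",
}
_COMPONENT_KEYS = {"drug", "dose", "dose_rule", "schedule", "max_cycles", "infused"}
_AE_KEYS = {"name", "incidence_intervention", "incidence_comparator", "cost", "disutility", "duration_years"}


@dataclass(frozen=True)
class RunConfig:
    """A validated run configuration.

    ``raw`` holds the normalized dictionary; ``base_dir`` anchors
    relative CSV paths.
    """

    raw: dict
    base_dir: Path

    @property
    def locale(self) -> str:
        return self.raw["locale"]

    @property
    def population(self) -> str:
        return self.raw["population"]

    @property
    def settings(self) -> ModelSettings:
        s = self.raw["settings"]
        return ModelSettings(
            cycle_length_days=s["cycle_length_days"],
            horizon_years=s["horizon_years"],
            discount_rate_annual=s["discount_rate_annual"],
            half_cycle_correction=s["half_cycle_correction"],
        )

    @property
    def wtp(self) -> float:
        return float(self.raw["wtp_per_qaly"])

    @property
    def arm_names(self) -> tuple[str, str]:
        """(intervention, comparator) in declared roles."""
        arms = self.raw["arms"]
        inter = [k for k, v in arms.items() if v.get("role") == "intervention"]
        comp = [k for k, v in arms.items() if v.get("role") == "comparator"]
        return inter[0], comp[0]


def _validate(raw: dict, base_dir: Path) -> list[str]:
    errors: list[str] = []

    def check_keys(mapping, allowed, where):
        for k in mapping:
            if k not in allowed:
                errors.append(f"{where}: unknown key {k!r}")

    def require(mapping, key, where, types=None):
        if key not in mapping:
            errors.append(f"{where}: missing required key {key!r}")
            return None
        val = mapping[key]
        if types is not None and not isinstance(val, types):
            errors.append(f"{where}.{key}: expected {types}, got {type(val).__name__}")
            return None
        return val

    if not isinstance(raw, dict):
        return ["configuration root must be a mapping"]
    check_keys(raw, _TOP_KEYS, "top level")

    loc = require(raw, "locale", "top level", str)
    if loc is not None and loc not in ("us", "china"):
        errors.append(f"locale: expected 'us' or 'china', got {loc!r}")
    pop = require(raw, "population", "top level", str)
    if pop is not None and pop not in ("itt", "cns"):
        errors.append(f"population: expected 'itt' or 'cns', got {pop!r}")

    settings = require(raw, "settings", "top level", dict)
    if settings is not None:
        check_keys(settings, _SETTINGS_KEYS, "settings")
        rate = settings.get("discount_rate_annual")
        if rate is not None and not (0.0 <= rate < 1.0):
            errors.append(f"settings.discount_rate_annual: must lie in [0, 1), got {rate}")
        for key in ("cycle_length_days", "horizon_years"):
            v = settings.get(key)
            if v is not None and v <= 0:
                errors.append(f"settings.{key}: must be positive, got {v}")

    wtp = require(raw, "wtp_per_qaly", "top level", (int, float))
    if wtp is not None and wtp < 0:
        errors.append(f"wtp_per_qaly: must be non-negative, got {wtp}")
    crit = raw.get("selection_criterion", "aic")
    if crit not in ("aic", "bic"):
        errors.append(f"selection_criterion: expected 'aic' or 'bic', got {crit!r}")
    mode = raw.get("hr_mode", "proportional_hazards")
    if mode not in ("proportional_hazards", "rate_multiply"):
        errors.append(f"hr_mode: unknown mode {mode!r}")

    econ = require(raw, "economics", "top level", dict)
    if econ is not None:
        check_keys(econ, _ECON_KEYS, "economics")
        for key in _ECON_KEYS - {"drug_prices_per_mg"}:
            v = require(econ, key, "economics", (int, float))
            if v is not None and v < 0:
                errors.append(f"economics.{key}: must be non-negative, got {v}")
        prices = require(econ, "drug_prices_per_mg", "economics", dict)
        if prices is not None:
            for drug, price in prices.items():
                if not isinstance(price, (int, float)) or price < 0:
                    errors.append(f"economics.drug_prices_per_mg.{drug}: invalid price {price!r}")

    utils = require(raw, "utilities", "top level", dict)
    if utils is not None:
        for key in ("pfs", "pd"):
            v = require(utils, key, "utilities", (int, float))
            if v is not None and not (0.0 <= v <= 1.0):
                errors.append(f"utilities.{key}: must lie in [0, 1], got {v}")

    for i, ae in enumerate(raw.get("adverse_events", [])):
        where = f"adverse_events[{i}]"
        if not isinstance(ae, dict):
            errors.append(f"{where}: expected a mapping")
            continue
        check_keys(ae, _AE_KEYS, where)
        for key in _AE_KEYS:
            require(ae, key, where)
        for key in ("incidence_intervention", "incidence_comparator"):
            v = ae.get(key)
            if isinstance(v, (int, float)) and not (0.0 <= v <= 1.0):
                errors.append(f"{where}.{key}: incidence outside [0, 1]: {v}")

    arms = require(raw, "arms", "top level", dict)
    roles = []
    if arms is not None:
        for arm_name, arm in arms.items():
            where = f"arms.{arm_name}"
            if not isinstance(arm, dict):
                errors.append(f"{where}: expected a mapping")
                continue
            check_keys(arm, _ARM_KEYS, where)
            role = require(arm, "role", where, str)
            roles.append(role)
            for key in ("discontinuation_fraction", "subsequent_fraction"):
                v = require(arm, key, where, (int, float))
                if v is not None and not (0.0 <= v <= 1.0):
                    errors.append(f"{where}.{key}: must lie in [0, 1], got {v}")
            v = require(arm, "subsequent_cost_per_cycle", where, (int, float))
            if v is not None and v < 0:
                errors.append(f"{where}.subsequent_cost_per_cycle: negative cost {v}")
            regimen = require(arm, "regimen", where, list)
            if regimen is not None:
                for j, comp in enumerate(regimen):
                    cw = f"{where}.regimen[{j}]"
                    if not isinstance(comp, dict):
                        errors.append(f"{cw}: expected a mapping")
                        continue
                    check_keys(comp, _COMPONENT_KEYS, cw)
                    require(comp, "drug", cw, str)
                    d = require(comp, "dose", cw, (int, float))
                    if d is not None and d <= 0:
                        errors.append(f"{cw}.dose: must be positive, got {d}")
            has_curves = "curves" in arm
            has_fitted = "fitted" in arm
            needs_curves = arm.get("role") == "comparator" or pop != "cns"
            if needs_curves and not has_curves and not has_fitted:
                errors.append(f"{where}: needs either 'curves' or 'fitted' survival inputs")
            for source in ("curves", "fitted"):
                block = arm.get(source)
                if block is None:
                    continue
                if not isinstance(block, dict):
                    errors.append(f"{where}.{source}: expected a mapping")
                    continue
                for endpoint, entry in block.items():
                    ew = f"{where}.{source}.{endpoint}"
                    if endpoint not in ("pfs", "os"):
                        errors.append(f"{ew}: endpoint must be 'pfs' or 'os'")
                    if source == "curves":
                        for k in ("curve_csv", "risk_csv"):
                            p = entry.get(k) if isinstance(entry, dict) else None
                            if p is None:
                                errors.append(f"{ew}: missing {k!r}")
                            elif not (base_dir / p).exists():
                                errors.append(f"{ew}.{k}: file not found: {p}")
                    else:
                        fam = entry.get("family") if isinstance(entry, dict) else None
                        if fam not in FAMILIES:
                            errors.append(f"{ew}.family: unknown family {fam!r}")
                        params = entry.get("params") if isinstance(entry, dict) else None
                        if not isinstance(params, list) or not params:
                            errors.append(f"{ew}.params: expected a non-empty list")
        if sorted(r for r in roles if r) != ["comparator", "intervention"] and arms:
            errors.append("arms: exactly one 'intervention' and one 'comparator' role required")

    if pop == "cns" and "population_hrs" not in raw:
        errors.append("population_hrs: required for the CNS population (hr_pfs, hr_os)")
    hrs = raw.get("population_hrs")
    if hrs is not None:
        for key in ("hr_pfs", "hr_os"):
            v = hrs.get(key)
            if not isinstance(v, (int, float)) or v <= 0:
                errors.append(f"population_hrs.{key}: must be a positive number, got {v!r}")

    psa = raw.get("psa")
    if psa is not None:
        if not isinstance(psa.get("iterations", 1), int) or psa.get("iterations", 1) < 1:
            errors.append(f"psa.iterations: must be a positive integer")
        if not isinstance(psa.get("seed", 0), int):
            errors.append("psa.seed: must be an integer")
    return errors


def load_config(path: str | Path) -> RunConfig:
    """Load and strictly validate a YAML run configuration.

    All validation problems are collected and reported together, each
    naming its key.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base_dir = path.parent
    errors = _validate(raw, base_dir)
    if errors:
        raise ConfigError(errors)
    return RunConfig(raw=raw, base_dir=base_dir)


def config_from_dict(raw: dict, base_dir: str | Path = ".") -> RunConfig:
    """Validate an in-memory configuration dictionary."""
    errors = _validate(raw, Path(base_dir))
    if errors:
        raise ConfigError(errors)
    return RunConfig(raw=raw, base_dir=Path(base_dir))


# ---------------------------------------------------------------------------
# curve resolution: digitized CSVs -> pseudo-IPD -> fits -> selected spec
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResolvedCurves:
    """Selected survival curve per (arm, endpoint) plus the fit trail."""

    curves: dict  # (arm, endpoint) -> DistributionSpec
    fits: dict  # (arm, endpoint) -> list[SurvivalFit], ranked
    reconstructed_n: dict  # (arm, endpoint) -> pseudo-IPD size (0 if pre-fitted)


def resolve_curves(config: RunConfig) -> ResolvedCurves:
    """Reconstruct, fit and select every survival curve a run needs.

    Arms with ``fitted`` parameter blocks skip reconstruction and
    fitting; arms with ``curves`` blocks go through the full
    digitized-KM path.
    """
    curves: dict = {}
    fits: dict = {}
    n_rec: dict = {}
    crit = config.raw.get("selection_criterion", "aic")
    for arm_name, arm in config.raw["arms"].items():
        fitted = arm.get("fitted", {})
        curve_files = arm.get("curves", {})
        for endpoint in ("pfs", "os"):
            key = (arm_name, endpoint)
            if endpoint in fitted:
                entry = fitted[endpoint]
                curves[key] = DistributionSpec(entry["family"], tuple(entry["params"]))
                n_rec[key] = 0
            elif endpoint in curve_files:
                entry = curve_files[endpoint]
                km = DigitizedKM.from_csv(
                    config.base_dir / entry["curve_csv"],
                    config.base_dir / entry["risk_csv"],
                )
                ipd = expand_to_ipd(reconstruct_interval_counts(km))
                ranked = select_distribution(fit_all_families(ipd), crit)
                curves[key] = ranked[0].spec
                fits[key] = ranked
                n_rec[key] = len(ipd)
    return ResolvedCurves(curves, fits, n_rec)


# ---------------------------------------------------------------------------
# the re-evaluable model: base case, overrides, parameter definitions
# ---------------------------------------------------------------------------


class CEModel:
    """The cost-effectiveness model as a re-evaluable closure.

    Survival curves are resolved once at construction; every call to
    :meth:`evaluate` rebuilds arms and settings under a (possibly
    empty) parameter-override mapping and returns the incremental
    result. This single surface backs the base case, one-way and
    probabilistic sensitivity analysis, the price-threshold search and
    scenario runs.
    """

    def __init__(self, config: RunConfig, resolved: ResolvedCurves | None = None):
        self.config = config
        self.resolved = resolved if resolved is not None else resolve_curves(config)
        self.intervention_name, self.comparator_name = config.arm_names
        self._base_params = self._build_base_params()

    # -- parameters ---------------------------------------------------------

    def _build_base_params(self) -> dict[str, float]:
        raw = self.config.raw
        econ = raw["economics"]
        p: dict[str, float] = {}
        for drug, price in econ["drug_prices_per_mg"].items():
            p[f"price_{drug}"] = float(price)
        for key in (
            "egfr_testing_cost", "follow_up_cost_per_cycle", "bsc_cost_per_cycle",
            "end_of_life_cost", "infusion_cost_per_administration",
        ):
            p[key] = float(econ[key])
        p["bsa"] = float(econ["bsa"])
        p["weight"] = float(econ["weight"])
        p["utility_pfs"] = float(raw["utilities"]["pfs"])
        p["utility_pd"] = float(raw["utilities"]["pd"])
        p["discount_rate_annual"] = float(raw["settings"]["discount_rate_annual"])
        for arm_name, arm in raw["arms"].items():
            p[f"subsequent_cost_{arm_name}"] = float(arm["subsequent_cost_per_cycle"])
            p[f"subsequent_fraction_{arm_name}"] = float(arm["subsequent_fraction"])
            p[f"discontinuation_{arm_name}"] = float(arm["discontinuation_fraction"])
        included = self._included_aes()
        for arm_key, which in ((self.intervention_name, "a"), (self.comparator_name, "b")):
            cost, dec = ae_burden(included, which)
            p[f"ae_cost_{arm_key}"] = cost
            p[f"ae_qaly_decrement_{arm_key}"] = dec
        if raw.get("population_hrs"):
            p["hr_pfs"] = float(raw["population_hrs"]["hr_pfs"])
            p["hr_os"] = float(raw["population_hrs"]["hr_os"])
        return p

    def _included_aes(self) -> list[AdverseEventEntry]:
        table = [
            AdverseEventEntry(
                name=ae["name"],
                incidence_a=ae["incidence_intervention"],
                incidence_b=ae["incidence_comparator"],
                cost=ae["cost"],
                disutility=ae["disutility"],
                duration_years=ae["duration_years"],
            )
            for ae in self.config.raw.get("adverse_events", [])
        ]
        return filter_adverse_events(table)

    @property
    def base_params(self) -> dict[str, float]:
        return dict(self._base_params)

    def parameter_defs(self) -> list[ParameterDef]:
        """Uncertain-parameter definitions for OWSA and PSA.

        Roles follow the quantity's nature (cost / probability /
        utility / hr / bsa / weight); bounds default to +/-25% of base.
        The discount rate is varied 0-8% in one-way analysis but, as a
        methodological rather than sampling uncertainty, is excluded
        from the probabilistic analysis. Parameters with base 0 are
        skipped (they carry no uncertainty on a +/-25% rule).
        """
        defs: list[ParameterDef] = []
        roles = {
            "bsa": "bsa",
            "weight": "weight",
            "utility_pfs": "utility",
            "utility_pd": "utility",
            "hr_pfs": "hr",
            "hr_os": "hr",
        }
        for name, base in self._base_params.items():
            if name == "discount_rate_annual":
                continue
            if base == 0.0:
                continue
            if name in roles:
                role = roles[name]
            elif name.startswith(("subsequent_fraction", "discontinuation")):
                role = "probability"
            elif name.startswith("ae_qaly_decrement"):
                role = "utility"
            else:
                role = "cost"
            defs.append(ParameterDef(name=name, role=role, base=base))
        defs.append(
            ParameterDef(
                name="discount_rate_annual",
                role="probability",
                base=self._base_params["discount_rate_annual"],
                low=0.0,
                high=0.08,
            )
        )
        return defs

    def psa_parameter_defs(self) -> list[ParameterDef]:
        return [d for d in self.parameter_defs() if d.name != "discount_rate_annual"]

    # -- evaluation ---------------------------------------------------------

    def _arm_curves(self, arm_name: str, params: Mapping[str, float]):
        pfs = self.resolved.curves.get((arm_name, "pfs"))
        osc = self.resolved.curves.get((arm_name, "os"))
        if self.config.population == "cns" and arm_name == self.intervention_name:
            mode = self.config.raw.get("hr_mode", "proportional_hazards")
            base_pfs = self.resolved.curves[(self.comparator_name, "pfs")]
            base_os = self.resolved.curves[(self.comparator_name, "os")]
            pfs = HRAdjustedCurve(base_pfs, params["hr_pfs"], mode)
            osc = HRAdjustedCurve(base_os, params["hr_os"], mode)
        if pfs is None or osc is None:
            raise ConfigError([f"arms.{arm_name}: no survival curves available"])
        return pfs, osc

    def _build_arm(self, arm_name: str, which: str, params: Mapping[str, float]) -> ArmSpec:
        raw_arm = self.config.raw["arms"][arm_name]
        prices = {
            name[len("price_"):]: val for name, val in params.items() if name.startswith("price_")
        }
        locale = LocaleEconomics(
            name=self.config.locale,
            drug_prices_per_mg=prices,
            bsa=params["bsa"],
            weight=params["weight"],
            egfr_testing_cost=params["egfr_testing_cost"],
            follow_up_cost_per_cycle=params["follow_up_cost_per_cycle"],
            bsc_cost_per_cycle=params["bsc_cost_per_cycle"],
            end_of_life_cost=params["end_of_life_cost"],
            infusion_cost_per_administration=params["infusion_cost_per_administration"],
            discount_rate_annual=params["discount_rate_annual"],
            wtp_per_qaly=self.config.wtp,
        )
        components = tuple(
            RegimenComponent(
                drug=c["drug"],
                dose=c["dose"],
                dose_rule=c.get("dose_rule", "flat"),
                schedule=c.get("schedule", "per_cycle"),
                max_cycles=c.get("max_cycles"),
                infused=c.get("infused", False),
            )
            for c in raw_arm["regimen"]
        )
        pfs, osc = self._arm_curves(arm_name, params)
        # aggregate AE burden enters as a single expected entry so that
        # sensitivity overrides act on the aggregate directly
        ae = AdverseEventEntry(
            name="aggregate_ae_burden",
            incidence_a=1.0,
            incidence_b=1.0,
            cost=params[f"ae_cost_{arm_name}"],
            disutility=params[f"ae_qaly_decrement_{arm_name}"],
            duration_years=1.0,
        )
        return ArmSpec(
            name=arm_name,
            pfs_curve=pfs,
            os_curve=osc,
            regimen=Regimen(name=arm_name, components=components),
            post_progression=PostProgressionPolicy(
                subsequent_fraction=params[f"subsequent_fraction_{arm_name}"],
                subsequent_cost_per_cycle=params[f"subsequent_cost_{arm_name}"],
                discontinuation_fraction=params[f"discontinuation_{arm_name}"],
            ),
            utility_pfs=params["utility_pfs"],
            utility_pd=params["utility_pd"],
            adverse_events=(ae,),
            ae_arm="a",
            locale=locale,
        )

    def evaluate(self, overrides: Mapping[str, float] | None = None) -> CEResult:
        """Evaluate the model; an empty override mapping is the base case."""
        params = dict(self._base_params)
        if overrides:
            unknown = set(overrides) - set(params)
            if unknown:
                raise KeyError(f"unknown parameter overrides: {sorted(unknown)}")
            params.update({k: float(v) for k, v in overrides.items()})
        s = self.config.settings
        settings = ModelSettings(
            cycle_length_days=s.cycle_length_days,
            horizon_years=s.horizon_years,
            discount_rate_annual=params["discount_rate_annual"],
            half_cycle_correction=s.half_cycle_correction,
        )
        a = evaluate_arm(self._build_arm(self.intervention_name, "a", params), settings)
        b = evaluate_arm(self._build_arm(self.comparator_name, "b", params), settings)
        return incremental_analysis(a, b)

    def price_model(self, drug: str = "osimertinib"):
        """Closure mapping one drug's unit price to the CEResult."""
        key = f"price_{drug}"
        if key not in self._base_params:
            raise KeyError(f"no price parameter for drug {drug!r}")
        return lambda price: self.evaluate({key: price})


# ---------------------------------------------------------------------------
# end-to-end pipeline with artifacts on disk
# ---------------------------------------------------------------------------


def results_frame(ce: CEResult) -> pd.DataFrame:
    """Base-case results in a cost/QALY/LY/ICER table layout."""
    rows = []
    for arm, icer_q, icer_ly in (
        (ce.intervention, ce.icer_per_qaly, ce.icer_per_ly),
        (ce.comparator, None, None),
    ):
        rows.append(
            {
                "arm": arm.name,
                "cost": round(arm.cost, 2),
                "qalys": round(arm.qalys, 4),
                "life_years": round(arm.life_years, 4),
                "icer_per_qaly": None if icer_q is None else round(icer_q, 2),
                "icer_per_ly": None if icer_ly is None else round(icer_ly, 2),
            }
        )
    return pd.DataFrame(rows)


def fit_report_frame(resolved: ResolvedCurves) -> pd.DataFrame:
    rows = []
    for (arm, endpoint), ranked in sorted(resolved.fits.items()):
        for rank, fit in enumerate(ranked):
            rows.append(
                {
                    "arm": arm,
                    "endpoint": endpoint,
                    "rank": rank,
                    "family": fit.spec.family,
                    "params": ";".join(f"{v:.6g}" for v in fit.spec.params),
                    "log_likelihood": round(fit.log_likelihood, 4),
                    "aic": round(fit.aic, 4),
                    "bic": round(fit.bic, 4),
                    "n_obs": fit.n_obs,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> tuple[CEResult, CEModel]:
    """Full run: reconstruct -> fit -> select -> trace -> accrue -> incremental.

    If ``outdir`` is given, writes ``results.csv`` (per-arm totals and
    ICERs), ``fits.csv`` (every candidate fit, ranked), and one trace
    CSV per arm.
    """
    model = CEModel(config)
    ce = model.evaluate()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        results_frame(ce).to_csv(outdir / "results.csv", index=False)
        fr = fit_report_frame(model.resolved)
        if len(fr):
            fr.to_csv(outdir / "fits.csv", index=False)
        for arm in (ce.intervention, ce.comparator):
            if arm.trace is not None:
                arm.trace.to_frame().to_csv(outdir / f"trace_{arm.name}.csv", index=False)
    return ce, model
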