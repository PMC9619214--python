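"""Parametric survival distributions and maximum-likelihood fitting.

Four candidate families are supported, all parameterized on the time
scale of months:

* ``exponential`` — ``S(t) = exp(-lam*t)`` with rate ``lam > 0``.
* ``weibull`` — ``S(t) = exp(-lam * t**gamma)`` with scale ``lam > 0``
  and shape ``gamma > 0`` (proportional-hazards form; the
  accelerated-failure-time scale is ``lam**(-1/gamma)``).
* ``loglogistic`` — ``S(t) = 1 / (1 + (t/alpha)**beta)``; ``alpha`` is
  the median survival time.
* ``lognormal`` — ``S(t) = 1 - Phi((log t - mu) / sigma)``.

Fitting maximizes the right-censored log-likelihood
``sum_events log f(t) + sum_censored log S(t)`` over log-transformed
positive parameters (``mu`` of the lognormal is unconstrained), from
three fixed starting points, so fits are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, special, stats

Family = Literal["exponential", "weibull", "loglogistic", "lognormal"]

#: canonical family order, also the tie-break order in model selection
FAMILIES: tuple[str, ...] = ("exponential", "weibull", "loglogistic", "lognormal")

_N_PARAMS = {"exponential": 1, "weibull": 2, "loglogistic": 2, "lognormal": 2}


class FittingError(RuntimeError):
    """Raised when maximum-likelihood fitting cannot proceed or converge."""


@dataclass(frozen=True)
class DistributionSpec:
    """A named parametric survival distribution with its parameters.

    ``params`` ordering: exponential ``(lam,)``; weibull ``(lam, gamma)``;
    loglogistic ``(alpha, beta)``; lognormal ``(mu, sigma)``. Times are
    in months.
    """

    family: Family
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        p = tuple(float(v) for v in self.params)
        if len(p) != _N_PARAMS[self.family]:
            raise ValueError(
                f"{self.family} takes {_N_PARAMS[self.family]} parameters, got {len(p)}"
            )
        positive = p if self.family != "lognormal" else p[1:]
        if any(not np.isfinite(v) for v in p) or any(v <= 0 for v in positive):
            raise ValueError(f"invalid parameters for {self.family}: {p}")
        object.__setattr__(self, "params", p)

    def survival(self, t):
        return survival_at(self, t)

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.family]


@dataclass(frozen=True)
class SurvivalFit:
    """A fitted distribution plus its likelihood-based fit statistics."""

    spec: DistributionSpec
    log_likelihood: float
    n_obs: int
    aic: float = field(init=False)
    bic: float = field(init=False)

    def __post_init__(self) -> None:
        k = self.spec.n_params
        object.__setattr__(self, "aic", 2.0 * k - 2.0 * self.log_likelihood)
        object.__setattr__(self, "bic", k * np.log(self.n_obs) - 2.0 * self.log_likelihood)


def survival_at(spec: DistributionSpec, t):
    """Survival function S(t) of ``spec`` at time ``t`` (months).

    Accepts a scalar or array; ``t`` must be non-negative.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("survival_at requires t >= 0")
    p = spec.params
    if spec.family == "exponential":
        s = np.exp(-p[0] * t_arr)
    elif spec.family == "weibull":
        s = np.exp(-p[0] * t_arr ** p[1])
    elif spec.family == "loglogistic":
        s = 1.0 / (1.0 + (t_arr / p[0]) ** p[1])
    else:  # lognormal
        with np.errstate(divide="ignore"):
            z = np.where(t_arr > 0, (np.log(np.maximum(t_arr, 1e-300)) - p[0]) / p[1], -np.inf)
        s = stats.norm.sf(z)
    return float(s) if np.isscalar(t) or t_arr.ndim == 0 else s


def log_pdf(spec: DistributionSpec, t):
    """Log density of the event-time distribution at ``t > 0``."""
    t_arr = np.asarray(t, dtype=float)
    p = spec.params
    logt = np.log(t_arr)
    if spec.family == "exponential":
        return np.log(p[0]) - p[0] * t_arr
    if spec.family == "weibull":
        lam, gam = p
        return np.log(lam) + np.log(gam) + (gam - 1.0) * logt - lam * t_arr ** gam
    if spec.family == "loglogistic":
        alpha, beta = p
        z = beta * (logt - np.log(alpha))
        # f(t) = (beta/alpha)(t/alpha)^(beta-1) / (1+(t/alpha)^beta)^2
        return np.log(beta) - logt + z - 2.0 * np.logaddexp(0.0, z)
    mu, sigma = p
    z = (logt - mu) / sigma
    return -0.5 * z * z - logt - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)


def median_survival(spec: DistributionSpec) -> float:
    """Closed-form median: the time t with S(t) = 1/2."""
    p = spec.params
    if spec.family == "exponential":
        return float(np.log(2.0) / p[0])
    if spec.family == "weibull":
        return float((np.log(2.0) / p[0]) ** (1.0 / p[1]))
    if spec.family == "loglogistic":
        return float(p[0])
    return float(np.exp(p[0]))


def mean_survival(spec: DistributionSpec, horizon: float | None = None) -> float:
    """Mean survival time in months, optionally restricted to ``horizon``.

    The unrestricted log-logistic mean diverges for shape <= 1; pass a
    horizon for a restricted mean in that case.
    """
    if horizon is None:
        p = spec.params
        if spec.family == "exponential":
            return float(1.0 / p[0])
        if spec.family == "weibull":
            return float(p[0] ** (-1.0 / p[1]) * special.gamma(1.0 + 1.0 / p[1]))
        if spec.family == "loglogistic":
            alpha, beta = p
            if beta <= 1:
                raise ValueError("log-logistic mean diverges for shape <= 1; give a horizon")
            b = np.pi / beta
            return float(alpha * b / np.sin(b))
        mu, sigma = p
        return float(np.exp(mu + 0.5 * sigma**2))
    from scipy.integrate import quad

    val, _ = quad(lambda t: survival_at(spec, t), 0.0, horizon, limit=200)
    return float(val)


def cycle_transition_prob(spec: DistributionSpec, t: float, u: float) -> float:
    """Probability of the event within the cycle [t, t+u) given survival to t.

    Returns ``1 - S(t+u)/S(t)``; for the exponential family this is
    independent of ``t``. When all mass is already absorbed (S(t) = 0)
    the probability is 1, with a warning.
    """
    if t < 0 or u < 0:
        raise ValueError("t and u must be non-negative")
    s_t = survival_at(spec, t)
    if s_t <= 0.0:
        warnings.warn("S(t) = 0 at cycle start; transition probability set to 1")
        return 1.0
    p = 1.0 - survival_at(spec, t + u) / s_t
    return float(min(max(p, 0.0), 1.0))


def hr_adjusted_survival(
    s_ref: float,
    hr: float,
    mode: Literal["proportional_hazards", "rate_multiply"] = "proportional_hazards",
):
    """Adjust a reference survival probability by a hazard ratio.

    ``proportional_hazards`` applies ``S_ref**hr`` (a valid survival
    transform for any hr > 0). ``rate_multiply`` multiplies the survival
    probability itself by the ratio and clamps into [0, 1]; it is kept
    as a literal replication mode even though it is not a proper
    survival transform when ``hr * S > 1``.
    """
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    s = np.asarray(s_ref, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("reference survival must lie in [0, 1]")
    if mode == "proportional_hazards":
        out = s**hr
    elif mode == "rate_multiply":
        out = np.clip(hr * s, 0.0, 1.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(out) if np.isscalar(s_ref) else out


@dataclass(frozen=True)
class HRAdjustedCurve:
    """A survival curve derived from a base curve via a hazard ratio.

    Used for subgroup analyses where only HRs (not curves) are reported:
    the subgroup intervention curve is the comparator curve raised to
    the HR (default), or rescaled on the survival-probability scale.
    """

    base: DistributionSpec
    hr: float
    mode: Literal["proportional_hazards", "rate_multiply"] = "proportional_hazards"

    def __post_init__(self) -> None:
        if self.hr <= 0:
            raise ValueError("hazard ratio must be positive")

    def survival(self, t):
        return hr_adjusted_survival(self.base.survival(t), self.hr, self.mode)


def _prepare_ipd(times: Sequence[float], events: Sequence[int]):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("times and events must be 1-d and equal length")
    if np.any(t < 0):
        raise ValueError("negative times in IPD")
    if e.sum() < 1:
        raise FittingError("at least one event is required to fit")
    # zero event times break log-likelihoods of all families; nudge
    t = np.where(t <= 0, 1e-6, t)
    return t, e


def _neg_loglik(family: str, theta: np.ndarray, t: np.ndarray, e: np.ndarray) -> float:
    if family == "lognormal":
        params = (theta[0], float(np.exp(theta[1])))
    else:
        params = tuple(float(np.exp(v)) for v in theta)
    try:
        spec = DistributionSpec(family, params)
    except (ValueError, OverflowError):
        return np.inf
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        ll_e = log_pdf(spec, t[e == 1]).sum() if np.any(e == 1) else 0.0
        s_c = survival_at(spec, t[e == 0]) if np.any(e == 0) else np.array([])
        ll_c = np.log(np.maximum(np.asarray(s_c), 1e-300)).sum() if s_c.size else 0.0
    val = -(ll_e + ll_c)
    return float(val) if np.isfinite(val) else np.inf


def _initial_points(family: str, t: np.ndarray, e: np.ndarray) -> list[np.ndarray]:
    """Three fixed starting points per family, derived from crude moments."""
    mean_t = float(t.mean())
    med_t = float(np.median(t))
    rate = max(e.sum() / t.sum(), 1e-8)
    if family == "lognormal":
        mu0 = np.log(max(med_t, 1e-6))
        return [np.array([mu0, np.log(s)]) for s in (0.5, 1.0, 2.0)]
    if family == "weibull":
        # lam such that median matches at each trial shape
        return [
            np.array([np.log(np.log(2.0) / max(med_t, 1e-6) ** g), np.log(g)])
            for g in (0.8, 1.0, 1.5)
        ]
    if family == "loglogistic":
        return [np.array([np.log(max(med_t, 1e-6)), np.log(b)]) for b in (0.8, 1.5, 3.0)]
    return [np.array([np.log(r)]) for r in (rate, rate * 0.5, 2.0 / max(mean_t, 1e-6))]


def fit_mle(ipd, family: Family) -> SurvivalFit:
    """Fit one parametric family to pseudo-IPD by maximum likelihood.

    ``ipd`` is any object with ``times`` and ``events`` sequences (an
    event flag of 1 marks an observed event, 0 right-censoring), e.g. a
    :class:`~survecon.reconstruct.PseudoIPD`. The exponential rate has
    the closed form d / sum(t); the two-parameter families are optimized
    numerically on log-transformed parameters with a three-point
    multi-start, making results deterministic.
    """
    t, e = _prepare_ipd(ipd.times, ipd.events)
    n = len(t)

    if family == "exponential":
        lam = float(e.sum() / t.sum())
        spec = DistributionSpec("exponential", (lam,))
        ll = -_neg_loglik("exponential", np.array([np.log(lam)]), t, e)
        return SurvivalFit(spec, ll, n)

    best: tuple[float, np.ndarray] | None = None
    for x0 in _initial_points(family, t, e):
        res = optimize.minimize(
            lambda th: _neg_loglik(family, th, t, e),
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 4000},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best[0]):
            best = (float(res.fun), res.x)
    if best is None or not np.isfinite(best[0]):
        raise FittingError(f"{family} fit did not converge on {n} observations")
    # polish with a gradient-free local refit from the winner
    res = optimize.minimize(
        lambda th: _neg_loglik(family, th, t, e),
        best[1],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 4000},
    )
    theta = res.x if res.fun <= best[0] else best[1]
    nll = min(float(res.fun), best[0])
    if family == "lognormal":
        params = (float(theta[0]), float(np.exp(theta[1])))
    else:
        params = tuple(float(np.exp(v)) for v in theta)
    return SurvivalFit(DistributionSpec(family, params), -nll, n)


def fit_all_families(ipd, families: Sequence[Family] = FAMILIES) -> list[SurvivalFit]:
    """Fit every candidate family to the same pseudo-IPD."""
    return [fit_mle(ipd, fam) for fam in families]


def select_distribution(
    fits: Sequence[SurvivalFit], criterion: Literal["aic", "bic"] = "aic"
) -> list[SurvivalFit]:
    """Rank fits ascending by AIC or BIC.

    Ties are broken by fewer parameters, then by the canonical family
    order (exponential, weibull, loglogistic, lognormal).
    """
    if not fits:
        raise ValueError("select_distribution requires at least one fit")
    if criterion not in ("aic", "bic"):
        raise ValueError(f"unknown criterion {criterion!r}")

    def key(fit: SurvivalFit):
        return (
            round(getattr(fit, criterion), 12),
            fit.spec.n_params,
            FAMILIES.index(fit.spec.family),
        )

    return sorted(fits, key=key)
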