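"""Parametric survival fitting, extrapolation and per-cycle transitions.

The trial observed two years of follow-up; the lifetime model needs event
probabilities far beyond that. Candidate families (exponential, Weibull,
log-normal, log-logistic) are fitted to the right-censored pseudo-IPD by
maximum likelihood, the best fit is selected by information criterion, and
the fitted closed form is used for all t — extrapolation is the same
analytic survival function evaluated beyond the data. "Logistic" in the
clinical literature's family list is read as log-logistic: the standard
survival family with support on t > 0.

Fitting is delegated to lifelines' univariate fitters. Each fitted model
carries its coefficient vector and covariance on the *estimation scale*
(location + log-scale, or log-parameters), which is what the probabilistic
sensitivity analysis samples from a multivariate normal.

The bridge into the Markov cohort model is :func:`per_cycle_transition`:
conditional exit probabilities over each 35-day cycle, with death and
progression to AML combined as independent competing risks and the total
exit split proportionally to the cause-specific cumulative-hazard
increments.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from lifelines import (
    ExponentialFitter,
    KaplanMeierFitter,
    LogLogisticFitter,
    LogNormalFitter,
    WeibullFitter,
)
from lifelines.exceptions import ConvergenceError
from scipy.special import erfc

__all__ = [
    "FAMILIES",
    "ParametricSurvModel",
    "KMCurve",
    "TransitionProbs",
    "FitError",
    "InsufficientDataError",
    "fit_km",
    "fit_parametric",
    "fit_all_families",
    "select_family",
    "survival_at",
    "per_cycle_transition",
    "transition_schedule",
]

# tie-break order: most parsimonious first
FAMILIES = ("exponential", "weibull", "lognormal", "loglogistic")

_SQRT2 = math.sqrt(2.0)


class FitError(RuntimeError):
    """Maximum-likelihood fit failed to converge; message carries diagnostics."""


class InsufficientDataError(ValueError):
    """Fewer than two observed events: the fit is not identified."""


@dataclass(frozen=True)
class ParametricSurvModel:
    """One fitted parametric survival model for one endpoint of one arm.

    ``params`` holds the family's natural parameters; ``coef``/``cov`` hold
    the estimate and covariance on the estimation scale used for sampling:

    - exponential: ``[log(rate)]`` with S(t) = exp(-rate * t)
    - weibull:     ``[log(shape), log(scale)]``, S(t) = exp(-(t/scale)^shape)
    - lognormal:   ``[mu, log(sigma)]``, S(t) = 1 - Phi((ln t - mu)/sigma)
    - loglogistic: ``[log(alpha), log(beta)]``, S(t) = 1/(1 + (t/alpha)^beta)
    """

    family: str
    coef: tuple[float, ...]
    cov: tuple[tuple[float, ...], ...] = None  # type: ignore[assignment]
    log_likelihood: float = math.nan
    n_events: int = 0
    n_censored: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        k = len(self.coef)
        expected = 1 if self.family == "exponential" else 2
        if k != expected:
            raise ValueError(f"{self.family} expects {expected} coefficients, got {k}")
        if self.cov is None:
            object.__setattr__(self, "cov", tuple(tuple(0.0 for _ in range(k)) for _ in range(k)))
        c = np.asarray(self.cov, dtype=float)
        if c.shape != (k, k):
            raise ValueError(f"covariance must be {k}x{k}, got {c.shape}")
        if not np.allclose(c, c.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh((c + c.T) / 2.0).min() < -1e-8:
            raise ValueError("covariance must be positive semi-definite")

    # -- natural-scale parameters ------------------------------------------
    @property
    def params(self) -> dict[str, float]:
        c = self.coef
        if self.family == "exponential":
            return {"rate": math.exp(c[0])}
        if self.family == "weibull":
            return {"shape": math.exp(c[0]), "scale": math.exp(c[1])}
        if self.family == "lognormal":
            return {"mu_log": c[0], "sigma_log": math.exp(c[1])}
        return {"alpha": math.exp(c[0]), "beta": math.exp(c[1])}

    @property
    def n_params(self) -> int:
        return len(self.coef)

    @property
    def n_obs(self) -> int:
        return self.n_events + self.n_censored

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.log_likelihood

    @property
    def bic(self) -> float:
        return self.n_params * math.log(max(self.n_obs, 1)) - 2.0 * self.log_likelihood

    # -- survival function -------------------------------------------------
    def survival(self, t_days):
        """S(t) by the family's closed form; valid for any t >= 0."""
        t = np.asarray(t_days, dtype=float)
        if np.any(t < 0):
            raise ValueError("t_days must be >= 0")
        p = self.params
        with np.errstate(divide="ignore"):
            if self.family == "exponential":
                s = np.exp(-p["rate"] * t)
            elif self.family == "weibull":
                s = np.exp(-((t / p["scale"]) ** p["shape"]))
            elif self.family == "lognormal":
                z = np.where(t > 0, (np.log(np.where(t > 0, t, 1.0)) - p["mu_log"]) / p["sigma_log"], -np.inf)
                s = 0.5 * erfc(z / _SQRT2)
            else:  # loglogistic
                s = 1.0 / (1.0 + (t / p["alpha"]) ** p["beta"])
        s = np.where(t == 0, 1.0, s)
        return float(s) if np.isscalar(t_days) or np.ndim(t_days) == 0 else s

    def with_coef(self, coef: Sequence[float]) -> "ParametricSurvModel":
        """Same family/metadata with a replaced coefficient vector (PSA use)."""
        return ParametricSurvModel(
            family=self.family,
            coef=tuple(float(c) for c in coef),
            cov=self.cov,
            log_likelihood=self.log_likelihood,
            n_events=self.n_events,
            n_censored=self.n_censored,
        )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "coef": list(self.coef),
            "cov": [list(row) for row in self.cov],
            "log_likelihood": self.log_likelihood,
            "n_events": self.n_events,
            "n_censored": self.n_censored,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParametricSurvModel":
        return cls(
            family=d["family"],
            coef=tuple(d["coef"]),
            cov=tuple(tuple(row) for row in d["cov"]),
            log_likelihood=d.get("log_likelihood", math.nan),
            n_events=d.get("n_events", 0),
            n_censored=d.get("n_censored", 0),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "ParametricSurvModel":
        return cls.from_dict(json.loads(s))

    # -- constructors from natural parameters ------------------------------
    @classmethod
    def exponential(cls, rate: float) -> "ParametricSurvModel":
        return cls("exponential", (math.log(rate),))

    @classmethod
    def weibull(cls, shape: float, scale: float) -> "ParametricSurvModel":
        return cls("weibull", (math.log(shape), math.log(scale)))

    @classmethod
    def lognormal(cls, mu_log: float, sigma_log: float) -> "ParametricSurvModel":
        return cls("lognormal", (mu_log, math.log(sigma_log)))

    @classmethod
    def loglogistic(cls, alpha: float, beta: float) -> "ParametricSurvModel":
        return cls("loglogistic", (math.log(alpha), math.log(beta)))


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: step function over the observed event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function value at time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _subset(ipd: pd.DataFrame, arm: str, endpoint: str) -> pd.DataFrame:
    sub = ipd[(ipd["arm"] == arm) & (ipd["endpoint"] == endpoint)]
    if sub.empty:
        raise ValueError(f"no records for arm={arm!r}, endpoint={endpoint!r}")
    return sub


def fit_km(ipd: pd.DataFrame, arm: str, endpoint: str) -> KMCurve:
    """Kaplan-Meier product-limit estimate for one arm/endpoint.

    Censoring flags are honoured; if no events are observed at all the
    curve is constant at 1 and a warning is emitted.
    """
    sub = _subset(ipd, arm, endpoint)
    if int(sub["event"].sum()) == 0:
        warnings.warn(
            f"no observed events for arm={arm!r}, endpoint={endpoint!r}; "
            "Kaplan-Meier curve is constant at 1",
            stacklevel=2,
        )
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time_days"], event_observed=sub["event"])
    table = kmf.event_table
    sf = kmf.survival_function_["KM_estimate"]
    return KMCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.to_numpy(dtype=float),
        at_risk=table["at_risk"].to_numpy(dtype=float),
    )


_FITTERS = {
    "exponential": (ExponentialFitter, ("lambda_",)),
    "weibull": (WeibullFitter, ("rho_", "lambda_")),
    "lognormal": (LogNormalFitter, ("mu_", "sigma_")),
    "loglogistic": (LogLogisticFitter, ("alpha_", "beta_")),
}


def _to_estimation_scale(family: str, natural: np.ndarray, cov_nat: np.ndarray):
    """Map natural parameters/covariance to the estimation scale (delta method)."""
    if family == "lognormal":
        coef = np.array([natural[0], math.log(natural[1])])
        jac_diag = np.array([1.0, 1.0 / natural[1]])
    elif family == "exponential":
        # lifelines lambda_ is the mean (1/rate); log(rate) = -log(lambda_)
        coef = np.array([-math.log(natural[0])])
        jac_diag = np.array([-1.0 / natural[0]])
    else:
        coef = np.log(natural)
        jac_diag = 1.0 / natural
    cov = (jac_diag[:, None] * cov_nat) * jac_diag[None, :]
    return coef, (cov + cov.T) / 2.0


def fit_parametric(ipd: pd.DataFrame, arm: str, endpoint: str, family: str) -> ParametricSurvModel:
    """Maximum-likelihood fit of one family to right-censored times.

    Requires at least two observed events. The coefficient covariance is
    derived from the observed information (via lifelines) and transformed
    to the estimation scale, where coefficients are asymptotically normal.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    sub = _subset(ipd, arm, endpoint)
    n_events = int(sub["event"].sum())
    if n_events < 2:
        raise InsufficientDataError(
            f"{n_events} observed event(s) for arm={arm!r}, endpoint={endpoint!r}; "
            "at least 2 are required for a parametric fit"
        )
    fitter_cls, names = _FITTERS[family]
    fitter = fitter_cls()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(sub["time_days"].to_numpy(), event_observed=sub["event"].to_numpy())
    except (ConvergenceError, ValueError) as exc:
        raise FitError(
            f"{family} fit failed for arm={arm!r}, endpoint={endpoint!r}: {exc}"
        ) from exc
    natural = np.array([getattr(fitter, n) for n in names], dtype=float)
    if not np.all(np.isfinite(natural)) or not np.all(natural > 0 if family != "lognormal" else np.isfinite(natural)):
        raise FitError(f"{family} fit returned non-finite parameters {natural}")
    cov_nat = fitter.variance_matrix_.loc[list(names), list(names)].to_numpy(dtype=float)
    coef, cov = _to_estimation_scale(family, natural, cov_nat)
    return ParametricSurvModel(
        family=family,
        coef=tuple(coef),
        cov=tuple(tuple(row) for row in cov),
        log_likelihood=float(fitter.log_likelihood_),
        n_events=n_events,
        n_censored=int(len(sub) - n_events),
    )


def fit_all_families(
    ipd: pd.DataFrame, arm: str, endpoint: str, families: Sequence[str] = FAMILIES
) -> list[ParametricSurvModel]:
    """Fit every candidate family, skipping (with a warning) ones that fail."""
    models = []
    for family in families:
        try:
            models.append(fit_parametric(ipd, arm, endpoint, family))
        except FitError as exc:
            warnings.warn(str(exc), stacklevel=2)
    if not models:
        raise FitError(f"all candidate families failed for arm={arm!r}, endpoint={endpoint!r}")
    return models


def select_family(
    models: Sequence[ParametricSurvModel], criterion: str = "aic"
) -> ParametricSurvModel:
    """Best-fitting model by information criterion (``aic`` default, ``bic`` optional).

    Ties are broken by family order, most parsimonious first.
    """
    if not models:
        raise ValueError("empty candidate list")
    if criterion not in ("aic", "bic"):
        raise ValueError(f"criterion must be 'aic' or 'bic', got {criterion!r}")
    return min(models, key=lambda m: (getattr(m, criterion), FAMILIES.index(m.family)))


def survival_at(model: ParametricSurvModel, t_days):
    """S(t) for a fitted model; the same closed form extrapolates beyond the data."""
    return model.survival(t_days)


class TransitionProbs(NamedTuple):
    """Per-cycle exit probabilities from the MDS state (competing risks)."""

    p_death: float
    p_aml: float
    absorbed: bool = False


_S_FLOOR = 1e-300


def transition_schedule(
    os_model: ParametricSurvModel,
    aml_model: ParametricSurvModel,
    n_cycles: int,
    cycle_days: float = 35.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`per_cycle_transition` for cycles 0..n_cycles-1.

    Returns arrays ``(p_death, p_aml)``; cycles whose interval starts
    after overall survival has reached zero get (1, 0), matching the
    scalar operation's absorbed-cohort convention.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    bounds = np.arange(n_cycles + 1, dtype=float) * cycle_days
    s_os = np.asarray(os_model.survival(bounds), dtype=float)
    s_aml = np.asarray(aml_model.survival(bounds), dtype=float)
    s0_os, s1_os = s_os[:-1], s_os[1:]
    s0_aml, s1_aml = s_aml[:-1], s_aml[1:]

    with np.errstate(divide="ignore", invalid="ignore"):
        q_death = np.clip(1.0 - np.where(s0_os > 0, s1_os / np.where(s0_os > 0, s0_os, 1.0), 0.0), 0.0, 1.0)
        q_aml = np.clip(1.0 - np.where(s0_aml > 0, s1_aml / np.where(s0_aml > 0, s0_aml, 1.0), 0.0), 0.0, 1.0)
        q_total = 1.0 - (1.0 - q_death) * (1.0 - q_aml)
        dh_death = np.log(np.maximum(s0_os, _S_FLOOR)) - np.log(np.maximum(s1_os, _S_FLOOR))
        dh_aml = np.where(
            s0_aml > 0,
            np.log(np.maximum(s0_aml, _S_FLOOR)) - np.log(np.maximum(s1_aml, _S_FLOOR)),
            0.0,
        )
        total_h = dh_death + dh_aml
        total_q = q_death + q_aml
        w_death = np.where(
            total_h > 0,
            dh_death / np.where(total_h > 0, total_h, 1.0),
            np.where(total_q > 0, q_death / np.where(total_q > 0, total_q, 1.0), 1.0),
        )
    p_death = q_total * w_death
    p_aml = q_total - p_death
    absorbed = s0_os <= 0.0
    p_death = np.where(absorbed, 1.0, p_death)
    p_aml = np.where(absorbed, 0.0, p_aml)
    zero = q_total <= 0.0
    p_death = np.where(zero & ~absorbed, 0.0, p_death)
    p_aml = np.where(zero & ~absorbed, 0.0, p_aml)
    return p_death, p_aml


def per_cycle_transition(
    os_model: ParametricSurvModel,
    aml_model: ParametricSurvModel,
    cycle_index: int,
    cycle_days: float = 35.0,
) -> TransitionProbs:
    """Conditional death/progression probabilities over one model cycle.

    For each endpoint X the raw per-cycle probability is the conditional
    exit q_X = 1 - S_X(t1)/S_X(t0) over [t0, t1) = [k*cd, (k+1)*cd). Death
    and AML progression are combined as independent competing risks —
    total exit 1 - (1-q_death)(1-q_aml) — and split in proportion to the
    cause-specific cumulative-hazard increments log S_X(t0) - log S_X(t1).
    If the overall-survival curve has already reached 0 at t0 the cohort
    is absorbed: (1, 0) is returned with ``absorbed=True``.
    """
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    if not cycle_days > 0:
        raise ValueError("cycle_days must be > 0")
    t0 = cycle_index * cycle_days
    t1 = t0 + cycle_days
    s0_os = os_model.survival(t0)
    if s0_os <= 0.0:
        return TransitionProbs(1.0, 0.0, absorbed=True)
    s1_os = os_model.survival(t1)
    s0_aml = aml_model.survival(t0)
    s1_aml = aml_model.survival(t1)

    q_death = min(max(1.0 - s1_os / s0_os, 0.0), 1.0)
    q_aml = 0.0 if s0_aml <= 0.0 else min(max(1.0 - s1_aml / s0_aml, 0.0), 1.0)

    q_total = 1.0 - (1.0 - q_death) * (1.0 - q_aml)
    if q_total <= 0.0:
        return TransitionProbs(0.0, 0.0)
    dh_death = math.log(max(s0_os, _S_FLOOR)) - math.log(max(s1_os, _S_FLOOR))
    dh_aml = 0.0
    if s0_aml > 0.0:
        dh_aml = math.log(max(s0_aml, _S_FLOOR)) - math.log(max(s1_aml, _S_FLOOR))
    total_h = dh_death + dh_aml
    if total_h <= 0.0:
        # hazard increments vanish at floating-point resolution; fall back
        # to the raw conditional probabilities as weights
        total_q = q_death + q_aml
        w_death = q_death / total_q if total_q > 0 else 1.0
    else:
        w_death = dh_death / total_h
    p_death = q_total * w_death
    p_aml = q_total - p_death
    return TransitionProbs(p_death, p_aml)
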