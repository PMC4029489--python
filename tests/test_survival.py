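"""Survival fitting, selection, extrapolation and competing-risk transitions."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from mdscea.simulate import generate_ipd
from mdscea.survival import (
    FAMILIES,
    InsufficientDataError,
    KMCurve,
    ParametricSurvModel,
    fit_km,
    fit_parametric,
    per_cycle_transition,
    select_family,
    survival_at,
    transition_schedule,
)
from test_simulate import one_arm


def ipd_from_times(times, events, arm="AZA", endpoint="OS"):
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(len(times))],
            "arm": arm,
            "endpoint": endpoint,
            "time_days": times,
            "event": events,
        }
    )


# ---------------------------------------------------------------- Kaplan-Meier
def test_km_textbook_product_limit():
    km = fit_km(ipd_from_times([1.0, 2.0, 3.0], [1, 1, 1]), "AZA", "OS")
    assert km.survival_at(1.0) == pytest.approx(2 / 3)
    assert km.survival_at(2.0) == pytest.approx(1 / 3)
    assert km.survival_at(3.0) == pytest.approx(0.0)
    assert km.survival_at(0.5) == 1.0


def test_km_all_censored_is_flat_one_with_warning():
    with pytest.warns(UserWarning, match="no observed events"):
        km = fit_km(ipd_from_times([5.0, 6.0], [0, 0]), "AZA", "OS")
    assert np.all(km.survival == 1.0)


def test_km_converges_to_exponential_closed_form():
    rate = 1 / 300.0
    rng = np.random.default_rng(2)
    t = rng.exponential(1 / rate, 10_000)
    km = fit_km(ipd_from_times(t, np.ones(len(t), dtype=int)), "AZA", "OS")
    sup = np.max(np.abs(km.survival - np.exp(-rate * km.times)))
    assert sup < 0.02


# ------------------------------------------------------------ parametric fits
def test_lognormal_parameter_recovery_within_3_se():
    mu, sigma = math.log(365.0), 0.8
    ipd = generate_ipd(one_arm(5_000, censor=1e12, seed=4))
    m = fit_parametric(ipd, "AZA", "OS", "lognormal")
    se_mu = math.sqrt(m.cov[0][0])
    assert abs(m.params["mu_log"] - mu) < 3 * se_mu
    # sigma is estimated on the log scale
    se_logsigma = math.sqrt(m.cov[1][1])
    assert abs(math.log(m.params["sigma_log"]) - math.log(sigma)) < 3 * se_logsigma


def test_exponential_mle_matches_closed_form():
    # with right censoring the exponential MLE is events / total observed time
    rng = np.random.default_rng(8)
    raw = rng.exponential(250.0, 2_000)
    t = np.minimum(raw, 400.0)
    e = (raw <= 400.0).astype(int)
    m = fit_parametric(ipd_from_times(t, e), "AZA", "OS", "exponential")
    assert m.params["rate"] == pytest.approx(e.sum() / t.sum(), rel=1e-5)
    assert m.n_events == int(e.sum())
    assert m.n_censored == int((1 - e).sum())


def test_single_event_is_insufficient():
    with pytest.raises(InsufficientDataError):
        fit_parametric(ipd_from_times([5.0, 6.0, 7.0], [1, 0, 0]), "AZA", "OS", "weibull")


def test_unknown_family_rejected():
    with pytest.raises(ValueError, match="family"):
        fit_parametric(ipd_from_times([1.0, 2.0], [1, 1]), "AZA", "OS", "gamma")


def test_covariance_is_positive_definite_and_loglik_finite():
    ipd = generate_ipd(one_arm(500, seed=9))
    for family in FAMILIES:
        m = fit_parametric(ipd, "AZA", "OS", family)
        eig = np.linalg.eigvalsh(np.asarray(m.cov))
        assert eig.min() > 0
        assert math.isfinite(m.log_likelihood)


# ------------------------------------------------------------ model selection
def fake_model(family, aic):
    # AIC = 2k - 2ll  =>  ll = k - aic/2
    k = 1 if family == "exponential" else 2
    coef = (0.0,) if family == "exponential" else (0.0, 0.0)
    return ParametricSurvModel(family=family, coef=coef, log_likelihood=k - aic / 2.0)


def test_select_family_is_argmin_aic():
    models = [fake_model("exponential", 100), fake_model("weibull", 98), fake_model("lognormal", 103)]
    assert select_family(models).family == "weibull"


def test_select_family_single_candidate_and_empty():
    only = fake_model("loglogistic", 50)
    assert select_family([only]) is only
    with pytest.raises(ValueError):
        select_family([])


def test_select_family_tie_breaks_by_parsimony_order():
    tied = [fake_model("lognormal", 100), fake_model("exponential", 100)]
    assert select_family(tied).family == "exponential"


def test_select_family_bic_criterion():
    a = fake_model("exponential", 100)
    b = fake_model("weibull", 99.5)  # lower AIC, but extra parameter
    object.__setattr__(a, "n_events", 100)
    object.__setattr__(b, "n_events", 100)
    assert select_family([a, b], criterion="aic").family == "weibull"
    assert select_family([a, b], criterion="bic").family == "exponential"


# ---------------------------------------------------------- survival function
@pytest.mark.parametrize(
    "model",
    [
        ParametricSurvModel.exponential(1 / 300.0),
        ParametricSurvModel.weibull(1.4, 400.0),
        ParametricSurvModel.lognormal(math.log(365.0), 0.8),
        ParametricSurvModel.loglogistic(365.0, 2.0),
    ],
    ids=lambda m: m.family,
)
def test_survival_function_basics(model):
    assert survival_at(model, 0.0) == 1.0
    grid = np.arange(0.0, 50 * 365.25, 1.0)
    s = model.survival(grid)
    assert np.all(np.diff(s) <= 1e-15)
    assert s[-1] < 0.05
    with pytest.raises(ValueError):
        survival_at(model, -1.0)


def test_lognormal_median_is_half():
    m = ParametricSurvModel.lognormal(math.log(500.0), 0.7)
    assert survival_at(m, 500.0) == pytest.approx(0.5, abs=1e-12)


def test_exponential_matches_quadrature_of_density():
    rate = 1 / 250.0
    m = ParametricSurvModel.exponential(rate)
    for t in (50.0, 400.0, 1500.0):
        integral, _ = integrate.quad(lambda u: rate * math.exp(-rate * u), t, np.inf)
        assert survival_at(m, t) == pytest.approx(integral, rel=1e-9)


def test_conditional_survival_telescopes():
    m = ParametricSurvModel.lognormal(math.log(600.0), 1.0)
    cd = 35.0
    prod = 1.0
    for k in range(40):
        prod *= m.survival((k + 1) * cd) / m.survival(k * cd)
    assert prod == pytest.approx(m.survival(40 * cd), rel=1e-10)


def test_serialization_roundtrip():
    ipd = generate_ipd(one_arm(300, seed=12))
    m = fit_parametric(ipd, "AZA", "OS", "lognormal")
    back = ParametricSurvModel.from_json(m.to_json())
    assert back == m
    assert back.survival(500.0) == m.survival(500.0)


# -------------------------------------------------------- per-cycle transition
def test_transition_single_risk_reduction():
    os_m = ParametricSurvModel.lognormal(math.log(600.0), 0.9)
    no_aml = ParametricSurvModel.exponential(1e-30)  # hazard ~ 0
    tp = per_cycle_transition(os_m, no_aml, 3)
    expected = 1.0 - os_m.survival(4 * 35.0) / os_m.survival(3 * 35.0)
    assert tp.p_aml == 0.0
    assert tp.p_death == pytest.approx(expected, rel=1e-12)


def test_transition_symmetry_equal_exponential_rates():
    a = ParametricSurvModel.exponential(1 / 400.0)
    b = ParametricSurvModel.exponential(1 / 400.0)
    tp = per_cycle_transition(a, b, 0)
    assert tp.p_death == pytest.approx(tp.p_aml, rel=1e-12)


def test_transition_matches_competing_risks_microsimulation():
    # independent latent exponential event times; cause = argmin within cycle 0
    lam1, lam2 = 1 / 300.0, 1 / 500.0
    rng = np.random.default_rng(123)
    n = 1_000_000
    t_death = rng.exponential(1 / lam1, n)
    t_aml = rng.exponential(1 / lam2, n)
    first = np.minimum(t_death, t_aml)
    exit_in_cycle = first < 35.0
    death_frac = np.mean(exit_in_cycle & (t_death <= t_aml))
    aml_frac = np.mean(exit_in_cycle & (t_aml < t_death))
    tp = per_cycle_transition(
        ParametricSurvModel.exponential(lam1), ParametricSurvModel.exponential(lam2), 0
    )
    se = math.sqrt(death_frac * (1 - death_frac) / n)
    assert abs(tp.p_death - death_frac) < 3 * se
    se = math.sqrt(aml_frac * (1 - aml_frac) / n)
    assert abs(tp.p_aml - aml_frac) < 3 * se
    assert tp.p_death + tp.p_aml <= 1.0


def test_transition_absorbed_cohort_flag():
    # Weibull with steep shape underflows to S = 0 well before the cycle start
    dead_os = ParametricSurvModel.weibull(8.0, 1.0)
    tp = per_cycle_transition(dead_os, ParametricSurvModel.exponential(1 / 300.0), 2)
    assert tp == (1.0, 0.0, True)


def test_transition_domain_errors():
    m = ParametricSurvModel.exponential(1 / 300.0)
    with pytest.raises(ValueError):
        per_cycle_transition(m, m, -1)
    with pytest.raises(ValueError):
        per_cycle_transition(m, m, 0, cycle_days=0.0)


def test_vectorized_schedule_equals_scalar_op():
    os_m = ParametricSurvModel.lognormal(math.log(745.0), 1.1)
    aml_m = ParametricSurvModel.weibull(1.2, 600.0)
    p_death, p_aml = transition_schedule(os_m, aml_m, 200)
    for k in (0, 1, 17, 100, 199):
        tp = per_cycle_transition(os_m, aml_m, k)
        assert p_death[k] == pytest.approx(tp.p_death, abs=1e-15)
        assert p_aml[k] == pytest.approx(tp.p_aml, abs=1e-15)
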