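"""Cohort engine: conservation, discounting, closed forms, monotonicity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdscea.cea import ArmResult
from mdscea.markov import (
    ArmSpec,
    HorizonWarning,
    ModelConfig,
    accumulate,
    discount_factor,
    run_cohort,
    step,
)
from mdscea.survival import ParametricSurvModel

YEAR_FRAC = 35.0 / 365.25


# ------------------------------------------------------------------ discount
def test_discount_factor_closed_forms():
    cfg = ModelConfig()
    assert discount_factor(0, cfg) == 1.0
    # one elapsed year exactly: 10 cycles of 36.525 days
    cfg_year = ModelConfig(cycle_days=36.525)
    assert discount_factor(10, cfg_year) == pytest.approx(1 / 1.03, rel=1e-12)
    cfg0 = ModelConfig(discount_rate=0.0)
    assert all(discount_factor(k, cfg0) == 1.0 for k in (0, 7, 520))
    with pytest.raises(ValueError):
        discount_factor(-1, cfg)


# ---------------------------------------------------------------------- step
def test_step_identity_and_aml_mortality():
    assert step((1.0, 0.0, 0.0), 0.0, 0.0, 0.0) == (1.0, 0.0, 0.0)
    assert step((0.0, 1.0, 0.0), 0.0, 0.0, 0.135) == (0.0, 0.865, 0.135)


def test_step_rejects_invalid_probabilities():
    with pytest.raises(ValueError):
        step((1.0, 0.0, 0.0), 0.7, 0.4, 0.0)
    with pytest.raises(ValueError):
        step((1.0, 0.0, 0.0), -0.1, 0.0, 0.0)


@settings(max_examples=200, derandomize=True)
@given(
    mds=st.floats(0, 1),
    aml_frac=st.floats(0, 1),
    p_exit=st.floats(0, 1),
    split=st.floats(0, 1),
    p_aml_death=st.floats(0, 1),
)
def test_step_conserves_mass(mds, aml_frac, p_exit, split, p_aml_death):
    aml = (1.0 - mds) * aml_frac
    dead = 1.0 - mds - aml
    p_death_mds = p_exit * split
    p_aml = p_exit - p_death_mds
    new = step((mds, aml, dead), p_death_mds, p_aml, p_aml_death)
    assert sum(new) == pytest.approx(1.0, abs=1e-12)
    assert new[2] >= dead - 1e-15  # death is absorbing and monotone


# ---------------------------------------------------------------- run_cohort
def test_aml_only_cohort_matches_geometric_closed_form(zero_cost_bundle):
    # mean sojourn of a geometric exit with p = 0.135 is 1/p cycles
    spec = ArmSpec(
        label="X",
        os_model=ParametricSurvModel.exponential(1e-30),
        aml_model=ParametricSurvModel.exponential(1e-30),
        cess_model=ParametricSurvModel.exponential(1e-30),
        costs=zero_cost_bundle,
        utility_mds=0.67,
        utility_aml=0.52,
    )
    cfg = ModelConfig(discount_rate=0.0, horizon_epsilon=1e-13, max_cycles=2000)
    trace = run_cohort(spec, cfg, start_state=(0.0, 1.0, 0.0))
    res = accumulate(trace)
    expected_ly = (1.0 / 0.135) * YEAR_FRAC
    assert res.ly == pytest.approx(expected_ly, rel=1e-9)
    assert res.qaly == pytest.approx(0.52 * expected_ly, rel=1e-9)
    assert res.cost == 0.0


def test_zero_hazards_accumulate_flat_qalys(zero_cost_bundle):
    spec = ArmSpec(
        label="X",
        os_model=ParametricSurvModel.exponential(1e-30),
        aml_model=ParametricSurvModel.exponential(1e-30),
        cess_model=ParametricSurvModel.exponential(1e-30),
        costs=zero_cost_bundle,
        utility_mds=0.67,
    )
    cfg = ModelConfig(discount_rate=0.0, max_cycles=10)
    with pytest.warns(HorizonWarning):
        trace = run_cohort(spec, cfg)
    assert trace.truncated
    res = accumulate(trace)
    assert res.qaly == pytest.approx(0.67 * 10 * YEAR_FRAC, rel=1e-12)
    assert res.ly == pytest.approx(10 * YEAR_FRAC, rel=1e-12)


def test_occupancy_conservation_and_monotone_death(aza_like_spec, config):
    trace = run_cohort(aza_like_spec, config)
    total = trace.mds + trace.aml + trace.dead
    assert np.max(np.abs(total - 1.0)) < 1e-12
    assert np.all(np.diff(trace.dead) >= -1e-15)
    assert np.all((trace.mds >= 0) & (trace.aml >= 0))
    assert np.all(trace.cost_discounted <= trace.cost_undiscounted + 1e-12)


def test_qaly_equals_ly_with_unit_utilities(zero_cost_bundle):
    spec = ArmSpec(
        label="X",
        os_model=ParametricSurvModel.lognormal(math.log(500.0), 1.0),
        aml_model=ParametricSurvModel.lognormal(math.log(400.0), 1.0),
        cess_model=ParametricSurvModel.weibull(1.3, 300.0),
        costs=zero_cost_bundle,
        utility_mds=1.0,
        utility_aml=1.0,
    )
    res = accumulate(run_cohort(spec, ModelConfig(discount_rate=0.0)))
    assert res.qaly == pytest.approx(res.ly, rel=1e-12)


def test_higher_death_hazard_never_increases_life_years(zero_cost_bundle):
    rng = np.random.default_rng(21)
    cfg = ModelConfig()
    for _ in range(10):
        rate = rng.uniform(1 / 2000.0, 1 / 200.0)
        bump = rng.uniform(1.01, 2.0)
        def ly(r):
            spec = ArmSpec(
                label="X",
                os_model=ParametricSurvModel.exponential(r),
                aml_model=ParametricSurvModel.lognormal(math.log(400.0), 1.0),
                cess_model=ParametricSurvModel.weibull(1.3, 300.0),
                costs=zero_cost_bundle,
            )
            return accumulate(run_cohort(spec, cfg)).ly
        assert ly(rate * bump) <= ly(rate) + 1e-12


def test_truncation_insensitivity_at_default_epsilon(aza_like_spec):
    base = accumulate(run_cohort(aza_like_spec, ModelConfig(max_cycles=2000)))
    finer = accumulate(
        run_cohort(aza_like_spec, ModelConfig(horizon_epsilon=5e-7, max_cycles=2000))
    )
    for attr in ("cost", "ly", "qaly"):
        assert getattr(finer, attr) == pytest.approx(getattr(base, attr), rel=1e-4)


def test_single_session_forces_off_treatment_after_first_cycle(bundles):
    spec = ArmSpec(
        label="SDC",
        os_model=ParametricSurvModel.lognormal(math.log(480.0), 1.1),
        aml_model=ParametricSurvModel.lognormal(math.log(365.0), 1.0),
        cess_model=ParametricSurvModel.weibull(1.3, 400.0),
        costs=bundles["SDC"],
        utility_mds=0.66,
        single_session=True,
    )
    trace = run_cohort(spec, ModelConfig())
    assert trace.on_treatment_frac[0] == 1.0
    assert np.all(trace.on_treatment_frac[1:] == 0.0)


def test_on_treatment_fraction_follows_cessation_curve(aza_like_spec, config):
    trace = run_cohort(aza_like_spec, config)
    expected = aza_like_spec.cess_model.survival(trace.cycle * config.cycle_days)
    assert np.allclose(trace.on_treatment_frac, expected, atol=1e-12)


def test_half_cycle_correction_reduces_totals_by_less_than_one_cycle(aza_like_spec):
    plain = accumulate(run_cohort(aza_like_spec, ModelConfig()))
    hcc = accumulate(run_cohort(aza_like_spec, ModelConfig(half_cycle_correction=True)))
    assert hcc.ly < plain.ly
    assert plain.ly - hcc.ly < YEAR_FRAC


# ---------------------------------------------------------------- accumulate
def test_accumulate_empty_and_identity(aza_like_spec, config):
    import mdscea.markov as mk

    empty = mk.CohortTrace(
        arm="X",
        cycle=np.array([], dtype=int),
        mds=np.array([]),
        aml=np.array([]),
        dead=np.array([]),
        on_treatment_frac=np.array([]),
        cost_undiscounted=np.array([]),
        cost_discounted=np.array([]),
        ly_discounted=np.array([]),
        qaly_discounted=np.array([]),
    )
    res = accumulate(empty)
    assert (res.cost, res.ly, res.qaly) == (0.0, 0.0, 0.0)

    trace = run_cohort(aza_like_spec, config)
    res = accumulate(trace)
    # high-precision summation oracle
    assert res.cost == pytest.approx(math.fsum(trace.cost_discounted), rel=1e-9)
    assert res.ly == pytest.approx(math.fsum(trace.ly_discounted), rel=1e-9)
    assert res.qaly == pytest.approx(math.fsum(trace.qaly_discounted), rel=1e-9)


def test_cohort_totals_match_individual_microsimulation(aza_like_spec):
    """Deterministic cohort vs a 100,000-patient first-order simulation."""
    from mdscea.survival import transition_schedule

    cfg = ModelConfig()
    trace = run_cohort(aza_like_spec, cfg)
    cohort = accumulate(trace)

    n = 100_000
    rng = np.random.default_rng(77)
    n_cycles = cfg.max_cycles
    p_death, p_aml = transition_schedule(
        aza_like_spec.os_model, aza_like_spec.aml_model, n_cycles, cfg.cycle_days
    )
    on = aza_like_spec.cess_model.survival(np.arange(n_cycles) * cfg.cycle_days)
    disc = (1.03) ** (-(np.arange(n_cycles) * cfg.cycle_days / 365.25))
    c_on = aza_like_spec.costs.cost_mds_on
    c_off = aza_like_spec.costs.cost_mds_off
    c_aml = aza_like_spec.costs.cost_aml

    state = np.zeros(n, dtype=np.int8)  # 0=MDS, 1=AML, 2=dead
    cost = np.zeros(n)
    ly = np.zeros(n)
    qaly = np.zeros(n)
    yf = cfg.cycle_days / 365.25
    for k in range(n_cycles):
        mds = state == 0
        aml = state == 1
        if not (mds.any() or aml.any()):
            break
        cost[mds] += (on[k] * c_on + (1 - on[k]) * c_off) * disc[k]
        cost[aml] += c_aml * disc[k]
        ly[mds | aml] += yf * disc[k]
        qaly[mds] += 0.67 * yf * disc[k]
        qaly[aml] += 0.52 * yf * disc[k]
        u = rng.random(n)
        die_mds = mds & (u < p_death[k])
        to_aml = mds & ~die_mds & (u < p_death[k] + p_aml[k])
        die_aml = aml & (rng.random(n) < cfg.aml_mortality_per_cycle)
        state[die_mds | die_aml] = 2
        state[to_aml] = 1

    for name, sim in (("cost", cost), ("ly", ly), ("qaly", qaly)):
        se = sim.std(ddof=1) / math.sqrt(n)
        assert abs(getattr(cohort, name) - sim.mean()) < 3 * se, name
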