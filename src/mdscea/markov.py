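"""Lifetime Markov cohort simulation over 5-week cycles.

Three mutually exclusive states: MDS (the starting state, on first-line
treatment), AML after progression, and death. Each cycle the MDS cohort
exits by death or progression at the rates implied by the fitted
overall-survival and time-to-AML curves (see
:func:`mdscea.survival.per_cycle_transition`); the AML cohort dies at a
constant arm-independent probability per cycle (0.135 by default). Being
on vs off first-line treatment is not a separate transition structure but
a cost weighting of the MDS state by the treatment-cessation curve: the
on-treatment fraction at cycle k is S_cess(k * cycle_days), forced to the
first cycle only for the single-session standard-dose chemotherapy arm.
AML occupants always accrue the best-supportive-care cost pattern.

Costs and utilities accrue on cycle-start occupancy and transitions apply
at cycle end; an optional half-cycle correction averages start and end
occupancy instead. Costs and effects are discounted at an annual rate
(3% default) evaluated at cycle start. The run stops when the alive
fraction drops below ``horizon_epsilon`` or at the cycle cap (~50 years).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costing import StateCostBundle
from .survival import ParametricSurvModel, transition_schedule

__all__ = [
    "ModelConfig",
    "ArmSpec",
    "CohortTrace",
    "discount_factor",
    "step",
    "run_cohort",
    "accumulate",
    "HorizonWarning",
]


class HorizonWarning(UserWarning):
    """The cycle cap was reached with a non-negligible fraction still alive."""


@dataclass(frozen=True)
class ModelConfig:
    """Global model settings (defaults follow the reference analysis)."""

    cycle_days: float = 35.0
    discount_rate: float = 0.03
    aml_mortality_per_cycle: float = 0.135
    horizon_epsilon: float = 1e-6
    max_cycles: int = 520  # ~50 years of 5-week cycles
    half_cycle_correction: bool = False
    days_per_year: float = 365.25

    def __post_init__(self):
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValueError(f"discount_rate must be in [0, 1), got {self.discount_rate}")
        if not 0.0 <= self.aml_mortality_per_cycle <= 1.0:
            raise ValueError(
                f"aml_mortality_per_cycle must be in [0, 1], got {self.aml_mortality_per_cycle}"
            )
        if not self.cycle_days > 0:
            raise ValueError(f"cycle_days must be > 0, got {self.cycle_days}")
        if self.max_cycles < 1:
            raise ValueError(f"max_cycles must be >= 1, got {self.max_cycles}")
        if not self.horizon_epsilon > 0:
            raise ValueError(f"horizon_epsilon must be > 0, got {self.horizon_epsilon}")

    @property
    def cycles_per_year(self) -> float:
        return self.days_per_year / self.cycle_days


@dataclass(frozen=True)
class ArmSpec:
    """Everything the cohort engine needs for one treatment arm."""

    label: str
    os_model: ParametricSurvModel
    aml_model: ParametricSurvModel
    cess_model: ParametricSurvModel
    costs: StateCostBundle
    utility_mds: float = 0.67
    utility_aml: float = 0.52
    single_session: bool = False

    def __post_init__(self):
        for name in ("utility_mds", "utility_aml"):
            u = getattr(self, name)
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {u}")


def discount_factor(cycle_index: int, config: ModelConfig) -> float:
    """(1+r)^(-t) with t the years elapsed at the start of the cycle."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    t_years = cycle_index * config.cycle_days / config.days_per_year
    return (1.0 + config.discount_rate) ** (-t_years)


def step(
    state: tuple[float, float, float],
    p_death_mds: float,
    p_aml: float,
    p_death_aml: float,
) -> tuple[float, float, float]:
    """Advance (mds, aml, dead) occupancy by one cycle; mass is conserved."""
    for name, p in (("p_death_mds", p_death_mds), ("p_aml", p_aml), ("p_death_aml", p_death_aml)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    if p_death_mds + p_aml > 1.0 + 1e-12:
        raise ValueError(
            f"p_death_mds + p_aml must be <= 1, got {p_death_mds} + {p_aml}"
        )
    mds, aml, dead = state
    new_mds = mds * (1.0 - p_death_mds - p_aml)
    new_aml = aml * (1.0 - p_death_aml) + mds * p_aml
    new_dead = dead + mds * p_death_mds + aml * p_death_aml
    return (new_mds, new_aml, new_dead)


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancy and discounted accruals of one cohort run."""

    arm: str
    cycle: np.ndarray
    mds: np.ndarray
    aml: np.ndarray
    dead: np.ndarray
    on_treatment_frac: np.ndarray
    cost_undiscounted: np.ndarray
    cost_discounted: np.ndarray
    ly_discounted: np.ndarray
    qaly_discounted: np.ndarray
    truncated: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": self.cycle,
                "mds": self.mds,
                "aml": self.aml,
                "dead": self.dead,
                "on_treatment_frac": self.on_treatment_frac,
                "cost_undiscounted": self.cost_undiscounted,
                "cost_discounted": self.cost_discounted,
                "ly_discounted": self.ly_discounted,
                "qaly_discounted": self.qaly_discounted,
            }
        )

    def __len__(self) -> int:
        return len(self.cycle)


def run_cohort(
    arm: ArmSpec,
    config: ModelConfig = ModelConfig(),
    start_state: tuple[float, float, float] = (1.0, 0.0, 0.0),
) -> CohortTrace:
    """Propagate the cohort from MDS-on-treatment to absorption.

    Cycle accruals use cycle-start occupancy (or the start/end average
    when ``config.half_cycle_correction``): cost = mds * (on_frac *
    cost_on + (1 - on_frac) * cost_off) + aml * cost_aml; life-years add
    (mds + aml) * cycle_days / days_per_year; QALYs weight the same time
    by the MDS and AML utilities. All three are recorded both raw and
    discounted at cycle start.
    """
    cd = config.cycle_days
    year_frac = cd / config.days_per_year
    cost_on = arm.costs.cost_mds_on
    cost_off = arm.costs.cost_mds_off
    cost_aml = arm.costs.cost_aml

    state = tuple(float(x) for x in start_state)
    if abs(sum(state) - 1.0) > 1e-9:
        raise ValueError(f"start_state must sum to 1, got {state}")

    # precompute the whole per-cycle probability / cost-weight schedule
    p_death_all, p_aml_all = transition_schedule(
        arm.os_model, arm.aml_model, config.max_cycles, cd
    )
    if arm.single_session:
        on_all = np.zeros(config.max_cycles)
        on_all[0] = 1.0
    else:
        on_all = np.asarray(
            arm.cess_model.survival(np.arange(config.max_cycles, dtype=float) * cd)
        )
    disc_all = (1.0 + config.discount_rate) ** (
        -(np.arange(config.max_cycles, dtype=float) * cd / config.days_per_year)
    )

    rows = {k: [] for k in (
        "cycle", "mds", "aml", "dead", "on", "cost_u", "cost_d", "ly_d", "qaly_d",
    )}
    truncated = False
    k = 0
    while True:
        mds, aml, dead = state
        alive = mds + aml
        if alive < config.horizon_epsilon:
            break
        if k >= config.max_cycles:
            truncated = True
            warnings.warn(
                f"arm {arm.label!r}: cycle cap {config.max_cycles} reached with "
                f"{alive:.3g} of the cohort still alive; totals are truncated",
                HorizonWarning,
                stacklevel=2,
            )
            break

        on_frac = float(on_all[k])
        next_state = step(
            state, float(p_death_all[k]), float(p_aml_all[k]), config.aml_mortality_per_cycle
        )

        if config.half_cycle_correction:
            w_mds = 0.5 * (mds + next_state[0])
            w_aml = 0.5 * (aml + next_state[1])
        else:
            w_mds, w_aml = mds, aml

        df = float(disc_all[k])
        cost = w_mds * (on_frac * cost_on + (1.0 - on_frac) * cost_off) + w_aml * cost_aml
        ly = (w_mds + w_aml) * year_frac
        qaly = (w_mds * arm.utility_mds + w_aml * arm.utility_aml) * year_frac

        rows["cycle"].append(k)
        rows["mds"].append(mds)
        rows["aml"].append(aml)
        rows["dead"].append(dead)
        rows["on"].append(on_frac)
        rows["cost_u"].append(cost)
        rows["cost_d"].append(cost * df)
        rows["ly_d"].append(ly * df)
        rows["qaly_d"].append(qaly * df)

        state = next_state
        k += 1

    return CohortTrace(
        arm=arm.label,
        cycle=np.asarray(rows["cycle"], dtype=int),
        mds=np.asarray(rows["mds"]),
        aml=np.asarray(rows["aml"]),
        dead=np.asarray(rows["dead"]),
        on_treatment_frac=np.asarray(rows["on"]),
        cost_undiscounted=np.asarray(rows["cost_u"]),
        cost_discounted=np.asarray(rows["cost_d"]),
        ly_discounted=np.asarray(rows["ly_d"]),
        qaly_discounted=np.asarray(rows["qaly_d"]),
        truncated=truncated,
    )


def accumulate(trace: CohortTrace):
    """Lifetime discounted totals of a trace as an :class:`~mdscea.cea.ArmResult`."""
    from .cea import ArmResult

    return ArmResult(
        label=trace.arm,
        cost=float(np.sum(trace.cost_discounted)),
        ly=float(np.sum(trace.ly_discounted)),
        qaly=float(np.sum(trace.qaly_discounted)),
    )
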