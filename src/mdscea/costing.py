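"""Per-cycle health-state costs (2012 euros, Spanish NHS perspective).

Each 5-week model cycle charges the cohort according to its state:

- MDS on first-line treatment: pre-medication, drug administration,
  pharmacology, follow-up visits, transfusions, concurrent medication and
  routine tests;
- MDS off treatment: the best-supportive-care resource pattern, including
  an annualized adverse-event line;
- AML: best-supportive-care pattern with its own follow-up/test mix.

The reference tables shipped under ``mdscea/data`` carry the published
unit costs, drug regimens, and per-cycle state cost components of the
Spanish azacitidine study; :func:`reference_bundles` returns them as
ready-to-use :class:`StateCostBundle` objects. The published per-cycle
pharmacology figures are carried verbatim as the canonical values (their
implied body-surface area varies slightly row to row, 1.687-1.700 m²);
:func:`drug_cost_per_cycle` provides the dose x BSA x days formula, with
optional whole-vial round-up, for constructing new regimens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

__all__ = [
    "DEFAULT_BSA",
    "UnitCosts",
    "DrugComponent",
    "DrugRegimen",
    "StateCostBundle",
    "drug_cost_per_cycle",
    "state_cost_per_cycle",
    "ae_cost_per_cycle",
    "load_unit_costs",
    "reference_bundles",
    "reference_regimens",
    "published_results",
]

#: body-surface area (m^2) back-calculated from the published low-dose
#: cytarabine row: 48.38 / (0.0271 * 150 * 7) = 1.700
DEFAULT_BSA = 1.70

_AE_TYPES = (
    "neutropenia",
    "leucopenia",
    "febrile_neutropenia",
    "pyrexia",
    "pneumonia",
    "sepsis",
)


def _data(name: str):
    return resources.files("mdscea.data").joinpath(name)


@dataclass(frozen=True)
class UnitCosts:
    """Published unit costs per resource (EUR 2012)."""

    inpatient_day: float = 742.91
    haematologist_visit: float = 62.22
    nurse_visit: float = 33.20
    biochemical_profile: float = 44.03
    bone_marrow_aspirate: float = 133.80
    full_blood_count: float = 6.08
    platelet_transfusion: float = 352.81
    blood_transfusion: float = 353.23
    adverse_events: Mapping[str, float] = field(
        default_factory=lambda: {
            "neutropenia": 68.0,
            "leucopenia": 68.0,
            "febrile_neutropenia": 3735.0,
            "pyrexia": 3735.0,
            "pneumonia": 3735.0,
            "sepsis": 3728.0,
        }
    )

    def __post_init__(self):
        for name in (
            "inpatient_day",
            "haematologist_visit",
            "nurse_visit",
            "biochemical_profile",
            "bone_marrow_aspirate",
            "full_blood_count",
            "platelet_transfusion",
            "blood_transfusion",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"unit cost {name} must be >= 0")
        for ae, cost in self.adverse_events.items():
            if cost < 0:
                raise ValueError(f"adverse-event cost {ae} must be >= 0")

    def scaled(self, factor: float) -> "UnitCosts":
        return UnitCosts(
            **{
                name: getattr(self, name) * factor
                for name in (
                    "inpatient_day",
                    "haematologist_visit",
                    "nurse_visit",
                    "biochemical_profile",
                    "bone_marrow_aspirate",
                    "full_blood_count",
                    "platelet_transfusion",
                    "blood_transfusion",
                )
            },
            adverse_events={k: v * factor for k, v in self.adverse_events.items()},
        )


def load_unit_costs() -> UnitCosts:
    """Unit costs from the packaged reference table."""
    df = pd.read_csv(_data("unit_costs.csv"))
    by_name = dict(zip(df["resource"], df["cost_eur"].astype(float)))
    ae = {k: by_name.pop(k) for k in _AE_TYPES}
    return UnitCosts(**by_name, adverse_events=ae)


@dataclass(frozen=True)
class DrugComponent:
    agent: str
    cost_per_mg: float  # EUR
    dose_mg_per_m2: float
    days_per_cycle: float

    def __post_init__(self):
        for name in ("cost_per_mg", "dose_mg_per_m2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{self.agent}: {name} must be > 0")
        if self.days_per_cycle < 0:
            raise ValueError(f"{self.agent}: days_per_cycle must be >= 0")


@dataclass(frozen=True)
class DrugRegimen:
    """A per-cycle combination of agents dosed by body-surface area."""

    name: str
    components: tuple[DrugComponent, ...]
    bsa: float = DEFAULT_BSA

    def __post_init__(self):
        if not self.bsa > 0:
            raise ValueError("bsa must be > 0")


def drug_cost_per_cycle(
    regimen: DrugRegimen,
    wastage_mode: str = "none",
    vial_sizes_mg: Mapping[str, float] | None = None,
) -> float:
    """Pharmacology cost of one cycle of ``regimen`` in EUR.

    ``wastage_mode='none'`` prices the administered milligrams exactly:
    sum of cost_per_mg * dose * BSA * days. ``'vial_round_up'`` rounds
    each administration up to whole vials of ``vial_sizes_mg[agent]``
    before pricing, charging the wasted remainder of the last vial.
    """
    if wastage_mode not in ("none", "vial_round_up"):
        raise ValueError(f"wastage_mode must be 'none' or 'vial_round_up', got {wastage_mode!r}")
    total = 0.0
    for comp in regimen.components:
        mg_per_admin = comp.dose_mg_per_m2 * regimen.bsa
        if wastage_mode == "vial_round_up":
            if not vial_sizes_mg or comp.agent not in vial_sizes_mg:
                raise ValueError(
                    f"vial_round_up requested but no vial size configured for {comp.agent!r}"
                )
            vial = vial_sizes_mg[comp.agent]
            mg_per_admin = math.ceil(mg_per_admin / vial) * vial
        total += comp.cost_per_mg * mg_per_admin * comp.days_per_cycle
    return total


@dataclass(frozen=True)
class StateCostBundle:
    """Per-cycle cost components (EUR) for one arm's three cost profiles."""

    mds_on: Mapping[str, float]
    mds_off: Mapping[str, float]
    aml: Mapping[str, float]

    def __post_init__(self):
        for state_name in ("mds_on", "mds_off", "aml"):
            for comp, value in getattr(self, state_name).items():
                if value < 0:
                    raise ValueError(f"{state_name} component {comp!r} must be >= 0")

    @property
    def cost_mds_on(self) -> float:
        return float(sum(self.mds_on.values()))

    @property
    def cost_mds_off(self) -> float:
        return float(sum(self.mds_off.values()))

    @property
    def cost_aml(self) -> float:
        return float(sum(self.aml.values()))

    def scaled(self, on: float = 1.0, off: float = 1.0, aml: float = 1.0) -> "StateCostBundle":
        """Multiplicatively rescaled copy (used by the sensitivity analysis)."""
        return StateCostBundle(
            mds_on={k: v * on for k, v in self.mds_on.items()},
            mds_off={k: v * off for k, v in self.mds_off.items()},
            aml={k: v * aml for k, v in self.aml.items()},
        )


def state_cost_per_cycle(bundle: StateCostBundle, state: str, on_treatment: bool = False) -> float:
    """Total per-cycle cost of a health state ('MDS' or 'AML')."""
    if state == "MDS":
        return bundle.cost_mds_on if on_treatment else bundle.cost_mds_off
    if state == "AML":
        return bundle.cost_aml
    raise ValueError(f"unknown state {state!r}; expected 'MDS' or 'AML'")


def ae_cost_per_cycle(
    annual_ae_rates: Mapping[str, float],
    unit_costs: UnitCosts,
    cycle_days: float = 35.0,
    days_per_year: float = 365.25,
) -> float:
    """Adverse-event cost of one cycle from annualized per-patient AE rates.

    Each AE type contributes annual_rate * (cycle_days / days_per_year) *
    episode cost; rates must be >= 0 and types must be priced in
    ``unit_costs.adverse_events``.
    """
    total = 0.0
    for ae, rate in annual_ae_rates.items():
        if ae not in unit_costs.adverse_events:
            known = ", ".join(sorted(unit_costs.adverse_events))
            raise ValueError(f"unknown adverse-event type {ae!r}; known types: {known}")
        if rate < 0:
            raise ValueError(f"adverse-event rate for {ae!r} must be >= 0")
        total += rate * (cycle_days / days_per_year) * unit_costs.adverse_events[ae]
    return total


def reference_bundles() -> dict[str, StateCostBundle]:
    """Published per-cycle state cost components for the four arms."""
    df = pd.read_csv(_data("state_costs.csv"))
    bundles: dict[str, StateCostBundle] = {}
    for arm, sub in df.groupby("arm", sort=False):
        parts = {
            state: dict(zip(s["component"], s["cost_eur"].astype(float)))
            for state, s in sub.groupby("state", sort=False)
        }
        bundles[arm] = StateCostBundle(
            mds_on=parts["mds_on"], mds_off=parts["mds_off"], aml=parts["aml"]
        )
    return bundles


def reference_regimens(bsa: float = DEFAULT_BSA) -> dict[str, DrugRegimen]:
    """Published drug regimens (azacitidine, low-dose and standard-dose combos)."""
    df = pd.read_csv(_data("regimens.csv"))
    regimens = {}
    for name, sub in df.groupby("regimen", sort=False):
        comps = tuple(
            DrugComponent(
                agent=r.agent,
                cost_per_mg=float(r.cost_per_mg_eur),
                dose_mg_per_m2=float(r.dose_mg_per_m2),
                days_per_cycle=float(r.days_per_cycle),
            )
            for r in sub.itertuples()
        )
        regimens[name] = DrugRegimen(name=name, components=comps, bsa=bsa)
    return regimens


def published_regimen_costs() -> dict[str, dict[str, float]]:
    """Published per-agent cost-per-cycle figures, keyed by regimen then agent."""
    df = pd.read_csv(_data("regimens.csv"))
    out: dict[str, dict[str, float]] = {}
    for r in df.itertuples():
        out.setdefault(r.regimen, {})[r.agent] = float(r.published_cost_per_cycle_eur)
    return out


def published_results() -> dict:
    """Published lifetime results of the reference analysis (validation fixture)."""
    import json

    with _data("published_results.json").open() as fh:
        return json.load(fh)
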