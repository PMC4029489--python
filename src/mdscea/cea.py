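"""Deterministic incremental cost-effectiveness analysis.

Given lifetime discounted totals per arm, this module computes pairwise
increments (ΔC, ΔLY, ΔQALY), incremental cost-effectiveness ratios
ICER = ΔC/ΔE, net monetary benefit NMB = WTP·ΔQALY − ΔC against a
willingness-to-pay threshold, and the pooled "conventional care regimen"
(CCR) comparator weighted by the trial's treatment pattern (BSC 79,
LDC 38, SDC 20 patients; azacitidine 110).

Two pooling conventions are provided. ``weight_outcomes`` (default)
takes patient-count-weighted means of the per-arm cost/LY/QALY totals on
both sides and forms one ICER from the pooled increments — the only
convention that yields a coherent pooled arm for downstream analyses.
``weight_icers`` instead averages the pairwise ICERs themselves with the
same weights, the convention described in the reference analysis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

__all__ = [
    "ArmResult",
    "Comparison",
    "WeightSet",
    "ThresholdDecision",
    "incremental",
    "pooled_result",
    "weighted_comparator",
    "threshold_decision",
    "results_table",
]


@dataclass(frozen=True)
class ArmResult:
    """Lifetime discounted totals for one strategy."""

    label: str
    cost: float
    ly: float
    qaly: float

    def __post_init__(self):
        for name in ("cost", "ly", "qaly"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite, got {getattr(self, name)!r}")


@dataclass(frozen=True)
class Comparison:
    """Incremental statistics of an intervention against a comparator.

    ICERs are ``None`` (undefined) when the corresponding effect
    difference is zero. ``dominant`` flags the intervention being at
    least as cheap and at least as effective (strictly better on one
    axis); ``dominated`` the reverse.
    """

    intervention: ArmResult
    comparator: ArmResult
    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_per_ly: float | None
    icer_per_qaly: float | None
    dominant: bool
    dominated: bool

    def to_dict(self) -> dict:
        return {
            "intervention": self.intervention.label,
            "comparator": self.comparator.label,
            "intervention_cost": self.intervention.cost,
            "comparator_cost": self.comparator.cost,
            "intervention_ly": self.intervention.ly,
            "comparator_ly": self.comparator.ly,
            "intervention_qaly": self.intervention.qaly,
            "comparator_qaly": self.comparator.qaly,
            "delta_cost": self.delta_cost,
            "delta_ly": self.delta_ly,
            "delta_qaly": self.delta_qaly,
            "icer_per_ly": self.icer_per_ly,
            "icer_per_qaly": self.icer_per_qaly,
            "dominant": self.dominant,
            "dominated": self.dominated,
        }


@dataclass(frozen=True)
class WeightSet:
    """Patient counts used to pool the conventional-care comparator arms."""

    counts: Mapping[str, float] = field(
        default_factory=lambda: {"AZA": 110.0, "BSC": 79.0, "LDC": 38.0, "SDC": 20.0}
    )

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("weights must be >= 0")
        if not any(c > 0 for c in self.counts.values()):
            raise ValueError("weights must not all be zero")

    def normalized(self, labels) -> dict[str, float]:
        missing = [l for l in labels if l not in self.counts]
        if missing:
            raise KeyError(f"no weight for arm(s): {', '.join(missing)}")
        total = sum(self.counts[l] for l in labels)
        if total <= 0:
            raise ValueError(f"total weight over {list(labels)} is zero")
        return {l: self.counts[l] / total for l in labels}


def incremental(intervention: ArmResult, comparator: ArmResult) -> Comparison:
    """Pairwise increments and ICERs; zero effect difference leaves the ICER undefined."""
    dc = intervention.cost - comparator.cost
    dly = intervention.ly - comparator.ly
    dqaly = intervention.qaly - comparator.qaly
    any_better = dly > 0 or dqaly > 0 or dc < 0
    any_worse = dly < 0 or dqaly < 0 or dc > 0
    return Comparison(
        intervention=intervention,
        comparator=comparator,
        delta_cost=dc,
        delta_ly=dly,
        delta_qaly=dqaly,
        icer_per_ly=dc / dly if dly != 0.0 else None,
        icer_per_qaly=dc / dqaly if dqaly != 0.0 else None,
        dominant=(dc <= 0 and dly >= 0 and dqaly >= 0 and any_better),
        dominated=(dc >= 0 and dly <= 0 and dqaly <= 0 and any_worse),
    )


def pooled_result(
    results: Mapping[str, ArmResult], weights: WeightSet, label: str = "CCR"
) -> ArmResult:
    """Count-weighted mean of per-arm lifetime totals."""
    w = weights.normalized(results.keys())
    return ArmResult(
        label=label,
        cost=sum(w[l] * r.cost for l, r in results.items()),
        ly=sum(w[l] * r.ly for l, r in results.items()),
        qaly=sum(w[l] * r.qaly for l, r in results.items()),
    )


def weighted_comparator(
    comparisons: Mapping[str, Comparison],
    weights: WeightSet,
    mode: str = "weight_outcomes",
) -> Comparison:
    """Pool the per-comparator comparisons into one intervention-vs-CCR row.

    ``comparisons`` maps comparator label -> pairwise :class:`Comparison`
    of the intervention against that arm. With ``weight_outcomes`` both
    sides' totals are count-weighted-averaged and the increments/ICERs
    recomputed from the pooled totals; with ``weight_icers`` the pairwise
    ICERs (and increments) are count-weighted-averaged directly.
    """
    if mode not in ("weight_outcomes", "weight_icers"):
        raise ValueError(f"mode must be 'weight_outcomes' or 'weight_icers', got {mode!r}")
    if not comparisons:
        raise ValueError("no comparisons to pool")
    labels = list(comparisons.keys())
    w = weights.normalized(labels)
    if mode == "weight_outcomes":
        pooled_comp = pooled_result(
            {l: c.comparator for l, c in comparisons.items()}, weights, label="CCR"
        )
        pooled_int = ArmResult(
            label=next(iter(comparisons.values())).intervention.label,
            cost=sum(w[l] * c.intervention.cost for l, c in comparisons.items()),
            ly=sum(w[l] * c.intervention.ly for l, c in comparisons.items()),
            qaly=sum(w[l] * c.intervention.qaly for l, c in comparisons.items()),
        )
        return incremental(pooled_int, pooled_comp)
    # weight_icers: average the pairwise ratios themselves
    if any(c.icer_per_ly is None or c.icer_per_qaly is None for c in comparisons.values()):
        raise ValueError("weight_icers requires every pairwise ICER to be defined")
    pooled_comp = pooled_result(
        {l: c.comparator for l, c in comparisons.items()}, weights, label="CCR"
    )
    pooled_int = ArmResult(
        label=next(iter(comparisons.values())).intervention.label,
        cost=sum(w[l] * c.intervention.cost for l, c in comparisons.items()),
        ly=sum(w[l] * c.intervention.ly for l, c in comparisons.items()),
        qaly=sum(w[l] * c.intervention.qaly for l, c in comparisons.items()),
    )
    dc = sum(w[l] * c.delta_cost for l, c in comparisons.items())
    dly = sum(w[l] * c.delta_ly for l, c in comparisons.items())
    dqaly = sum(w[l] * c.delta_qaly for l, c in comparisons.items())
    return Comparison(
        intervention=pooled_int,
        comparator=pooled_comp,
        delta_cost=dc,
        delta_ly=dly,
        delta_qaly=dqaly,
        icer_per_ly=sum(w[l] * c.icer_per_ly for l, c in comparisons.items()),
        icer_per_qaly=sum(w[l] * c.icer_per_qaly for l, c in comparisons.items()),
        dominant=(dc <= 0 and dly >= 0 and dqaly >= 0 and (dly > 0 or dqaly > 0 or dc < 0)),
        dominated=(dc >= 0 and dly <= 0 and dqaly <= 0 and (dly < 0 or dqaly < 0 or dc > 0)),
    )


@dataclass(frozen=True)
class ThresholdDecision:
    net_monetary_benefit: float
    cost_effective: bool


def threshold_decision(comparison: Comparison, wtp_per_qaly: float) -> ThresholdDecision:
    """NMB = WTP·ΔQALY − ΔC; cost-effective when strictly positive."""
    if wtp_per_qaly < 0:
        raise ValueError("wtp_per_qaly must be >= 0")
    nmb = wtp_per_qaly * comparison.delta_qaly - comparison.delta_cost
    return ThresholdDecision(net_monetary_benefit=nmb, cost_effective=nmb > 0)


def results_table(comparisons: Mapping[str, Comparison]) -> pd.DataFrame:
    """Tabular layout of pairwise (and pooled) comparisons for export."""
    return pd.DataFrame([c.to_dict() for c in comparisons.values()])


def write_results(comparisons: Mapping[str, Comparison], csv_path=None, json_path=None) -> None:
    table = results_table(comparisons)
    if csv_path is not None:
        table.to_csv(csv_path, index=False, float_format="%.6f")
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump({k: c.to_dict() for k, c in comparisons.items()}, fh, indent=2)
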