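"""Probabilistic sensitivity analysis (second-order Monte Carlo).

Every uncertain input is given a sampling distribution, one joint draw is
taken per iteration, the deterministic cohort model is re-run for every
arm under that draw, and the incremental results are collected:

- survival / time-to-AML / cessation curves: multivariate normal on the
  fitted coefficients (estimation scale) using the fit covariance;
- utilities and the per-cycle AML mortality: beta distributions matched
  by moments to the central value with a 95% interval of ±30% (or the
  empirical interval where one exists), truncated to [0, 1];
- state cost totals: normal multipliers with mean 1 and a 95% interval
  of ±30%, truncated at zero (dosing/resource-use uncertainty).

The ``dispersion_scale`` knob multiplies every spread; at 0 each draw
reproduces the deterministic point estimate exactly, which is the
collapse property the tests rely on. Outputs are the cost-effectiveness
plane (per-draw ΔC, ΔLY, ΔQALY per comparator, including the pooled
conventional-care comparator) and cost-effectiveness acceptability
curves: the fraction of draws with positive net monetary benefit across
a willingness-to-pay grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cea import ArmResult, WeightSet, incremental, pooled_result
from .markov import ArmSpec, HorizonWarning, ModelConfig, accumulate, run_cohort
from .survival import ParametricSurvModel

__all__ = [
    "BetaParam",
    "ArmUncertainty",
    "PSASpec",
    "PSAResult",
    "sample_parameters",
    "run_psa",
    "ceac",
]

logger = logging.getLogger(__name__)

#: half-width of a 95% normal interval expressed in standard deviations
_Z95 = 1.959963984540054


@dataclass(frozen=True)
class BetaParam:
    """A probability-scale parameter with mean and relative 95% half-width."""

    mean: float
    rel_range: float = 0.30

    def __post_init__(self):
        if not 0.0 <= self.mean <= 1.0:
            raise ValueError(f"mean must be in [0, 1], got {self.mean}")
        if self.rel_range < 0:
            raise ValueError("rel_range must be >= 0")


def _sample_beta(param: BetaParam, rng: np.random.Generator, scale: float) -> float:
    """Moment-matched beta draw; degenerate at the mean when the spread is 0.

    If the requested variance is infeasible for a beta with this mean
    (variance >= m(1-m)), the spread is truncated to the feasible bound
    and the truncation is logged.
    """
    z = rng.standard_normal()  # consumed even when degenerate: keeps streams aligned
    m = param.mean
    sd = scale * param.rel_range * m / _Z95
    if sd == 0.0 or m in (0.0, 1.0):
        return m
    var = sd * sd
    var_max = m * (1.0 - m)
    if var >= var_max:
        logger.warning(
            "beta moment matching infeasible for mean %.4f with sd %.4f; truncating", m, sd
        )
        var = 0.99 * var_max
    nu = var_max / var - 1.0
    a, b = m * nu, (1.0 - m) * nu
    # map the shared normal deviate through the beta quantile function so
    # that draws vary continuously with dispersion_scale
    from scipy.stats import beta as beta_dist, norm

    return float(min(max(beta_dist.ppf(norm.cdf(z), a, b), 0.0), 1.0))


def _sample_multiplier(rel_range: float, rng: np.random.Generator, scale: float) -> float:
    """Normal multiplier, mean 1, 95% interval ±rel_range, truncated at 0."""
    z = rng.standard_normal()
    return max(0.0, 1.0 + scale * rel_range / _Z95 * z)


def _cov_sqrt(cov: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root (eigendecomposition; robust to singular fits)."""
    w, v = np.linalg.eigh((cov + cov.T) / 2.0)
    w = np.clip(w, 0.0, None)
    return v @ np.diag(np.sqrt(w)) @ v.T


def _sample_model(
    model: ParametricSurvModel, rng: np.random.Generator, scale: float
) -> ParametricSurvModel:
    k = len(model.coef)
    z = rng.standard_normal(k)
    if scale == 0.0:
        return model
    coef = np.asarray(model.coef) + scale * (_cov_sqrt(np.asarray(model.cov)) @ z)
    return model.with_coef(coef)


@dataclass(frozen=True)
class ArmUncertainty:
    """Uncertain inputs for one arm: fitted curves, costs and MDS utility."""

    label: str
    os_model: ParametricSurvModel
    aml_model: ParametricSurvModel
    cess_model: ParametricSurvModel
    costs: "object"  # StateCostBundle
    utility_mds: BetaParam = BetaParam(0.67)
    cost_rel_range: float = 0.30
    single_session: bool = False


@dataclass(frozen=True)
class PSASpec:
    """Everything the PSA needs: per-arm uncertainty plus global parameters."""

    arms: Mapping[str, ArmUncertainty]
    intervention: str = "AZA"
    comparators: tuple[str, ...] = ("BSC", "LDC", "SDC")
    weights: WeightSet = field(default_factory=WeightSet)
    config: ModelConfig = field(default_factory=ModelConfig)
    utility_aml: BetaParam = BetaParam(0.52)
    aml_mortality: BetaParam = BetaParam(0.135)
    dispersion_scale: float = 1.0

    def __post_init__(self):
        missing = [
            l for l in (self.intervention, *self.comparators) if l not in self.arms
        ]
        if missing:
            raise ValueError(f"arm(s) without uncertainty spec: {', '.join(missing)}")


def sample_parameters(spec: PSASpec, rng: np.random.Generator) -> dict:
    """One coherent joint draw of all uncertain parameters.

    Returns ``{"arm_specs": {label: ArmSpec}, "aml_mortality": float,
    "utility_aml": float}``. Deterministic given the generator state; the
    AML utility and AML mortality are global (shared across arms), while
    curves, costs and the MDS utility are drawn per arm.
    """
    s = spec.dispersion_scale
    u_aml = _sample_beta(spec.utility_aml, rng, s)
    p_aml_death = _sample_beta(spec.aml_mortality, rng, s)
    arm_specs: dict[str, ArmSpec] = {}
    for label, arm in spec.arms.items():
        os_m = _sample_model(arm.os_model, rng, s)
        aml_m = _sample_model(arm.aml_model, rng, s)
        cess_m = _sample_model(arm.cess_model, rng, s)
        u_mds = _sample_beta(arm.utility_mds, rng, s)
        mult_on = _sample_multiplier(arm.cost_rel_range, rng, s)
        mult_off = _sample_multiplier(arm.cost_rel_range, rng, s)
        mult_aml = _sample_multiplier(arm.cost_rel_range, rng, s)
        arm_specs[label] = ArmSpec(
            label=label,
            os_model=os_m,
            aml_model=aml_m,
            cess_model=cess_m,
            costs=arm.costs.scaled(on=mult_on, off=mult_off, aml=mult_aml),
            utility_mds=u_mds,
            utility_aml=u_aml,
            single_session=arm.single_session,
        )
    return {"arm_specs": arm_specs, "aml_mortality": p_aml_death, "utility_aml": u_aml}


@dataclass(frozen=True)
class PSAResult:
    """Per-draw incremental results of the intervention vs each comparator."""

    draws: pd.DataFrame  # columns: draw, comparator, delta_cost, delta_ly, delta_qaly
    n_draws: int
    n_failed: int
    intervention: str
    seed: int | None = None

    def for_comparator(self, comparator: str) -> pd.DataFrame:
        sub = self.draws[self.draws["comparator"] == comparator]
        if sub.empty:
            raise KeyError(f"no draws recorded against comparator {comparator!r}")
        return sub


def run_psa(
    spec: PSASpec,
    n_draws: int = 50_000,
    rng: np.random.Generator | int | None = None,
) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty through the model.

    Per draw the cohort model is re-run for the intervention and every
    comparator; increments are recorded against each comparator and
    against the patient-count-pooled conventional-care arm ("CCR") when
    more than one comparator is present. Draws whose model run fails or
    returns non-finite totals are flagged and excluded; more than 5%
    failures aborts with an error, as that indicates a mis-specified
    sampling spec rather than bad luck.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    pool_ccr = len(spec.comparators) > 1
    records: list[tuple] = []
    n_failed = 0
    for draw in range(n_draws):
        params = sample_parameters(spec, rng)
        try:
            results: dict[str, ArmResult] = {}
            config = replace(spec.config, aml_mortality_per_cycle=params["aml_mortality"])
            with warnings.catch_warnings():
                # heavy-tailed draws routinely leave ~epsilon of the cohort
                # alive at the cycle cap; the truncation is negligible and
                # recorded per trace, so don't emit one warning per draw
                warnings.simplefilter("ignore", HorizonWarning)
                for label in (spec.intervention, *spec.comparators):
                    results[label] = accumulate(run_cohort(params["arm_specs"][label], config))
            comps = {
                c: incremental(results[spec.intervention], results[c])
                for c in spec.comparators
            }
            if any(
                not np.isfinite([x.delta_cost, x.delta_ly, x.delta_qaly]).all()
                for x in comps.values()
            ):
                raise FloatingPointError("non-finite incremental result")
        except Exception as exc:  # noqa: BLE001 - failed draws are data, not bugs
            n_failed += 1
            logger.warning("PSA draw %d failed: %s", draw, exc)
            continue
        for c, comp in comps.items():
            records.append((draw, c, comp.delta_cost, comp.delta_ly, comp.delta_qaly))
        if pool_ccr:
            pooled = pooled_result(
                {c: results[c] for c in spec.comparators}, spec.weights, label="CCR"
            )
            comp = incremental(results[spec.intervention], pooled)
            records.append((draw, "CCR", comp.delta_cost, comp.delta_ly, comp.delta_qaly))

    if n_failed > 0.05 * n_draws:
        raise RuntimeError(
            f"{n_failed}/{n_draws} PSA draws failed (> 5%); check the sampling spec"
        )
    draws = pd.DataFrame(
        records, columns=["draw", "comparator", "delta_cost", "delta_ly", "delta_qaly"]
    )
    return PSAResult(
        draws=draws,
        n_draws=n_draws,
        n_failed=n_failed,
        intervention=spec.intervention,
        seed=seed,
    )


def ceac(
    psa: PSAResult,
    wtp_grid: Sequence[float],
    comparators: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves over a willingness-to-pay grid.

    At each WTP the curve is the fraction of successful draws with
    NMB = WTP·ΔQALY − ΔC > 0. Returns a frame indexed by WTP with one
    column per comparator.
    """
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must not be empty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("wtp_grid must be strictly increasing")
    if psa.draws.empty:
        raise ValueError("PSA result contains no successful draws")
    if comparators is None:
        comparators = list(dict.fromkeys(psa.draws["comparator"]))
    out = {}
    for c in comparators:
        sub = psa.for_comparator(c)
        dq = sub["delta_qaly"].to_numpy()
        dc = sub["delta_cost"].to_numpy()
        nmb = grid[:, None] * dq[None, :] - dc[None, :]
        out[c] = (nmb > 0).mean(axis=1)
    return pd.DataFrame(out, index=pd.Index(grid, name="wtp_per_qaly"))
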