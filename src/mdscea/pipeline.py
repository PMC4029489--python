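"""End-to-end orchestration: simulate -> fit -> run -> compare -> PSA.

Each stage is an ordinary library call; :func:`run_pipeline` chains them,
optionally writes every artifact (pseudo-IPD, fitted models, cohort
traces, the incremental results table, PSA draws and acceptability
curves) to an output directory, and records a run manifest with the
resolved configuration, seeds, input digests and per-stage status so a
run is reproducible from the manifest alone. Numeric outputs are
byte-identical across reruns with the same seed; wall-clock timestamps
live only in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cea import (
    ArmResult,
    Comparison,
    incremental,
    threshold_decision,
    weighted_comparator,
    write_results,
)
from .config import Config
from .costing import reference_bundles
from .markov import ArmSpec, CohortTrace, accumulate, run_cohort
from .psa import ArmUncertainty, BetaParam, PSAResult, PSASpec, ceac, run_psa
from .simulate import ENDPOINTS, generate_ipd, read_ipd, write_ipd
from .survival import ParametricSurvModel, fit_all_families, select_family

__all__ = ["PipelineError", "PipelineResult", "fit_endpoint_models", "build_arm_specs", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and context."""


def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class PipelineResult:
    ipd: pd.DataFrame
    fits: dict[str, dict[str, ParametricSurvModel]]  # arm -> endpoint -> model
    traces: dict[str, CohortTrace]
    arm_results: dict[str, ArmResult]
    comparisons: dict[str, Comparison]
    psa: PSAResult | None
    ceac: pd.DataFrame | None
    manifest: dict


def fit_endpoint_models(
    ipd: pd.DataFrame,
    arms,
    criterion: str = "aic",
    families=None,
) -> dict[str, dict[str, ParametricSurvModel]]:
    """Best-fitting parametric model per arm and endpoint (auto selection)."""
    from .survival import FAMILIES

    fits: dict[str, dict[str, ParametricSurvModel]] = {}
    for arm in arms:
        fits[arm] = {}
        for endpoint in ENDPOINTS:
            models = fit_all_families(ipd, arm, endpoint, families or FAMILIES)
            best = select_family(models, criterion=criterion)
            logger.info("fit %s/%s -> %s (aic %.1f)", arm, endpoint, best.family, best.aic)
            fits[arm][endpoint] = best
    return fits


def build_arm_specs(
    fits: Mapping[str, Mapping[str, ParametricSurvModel]],
    config: Config,
    bundles=None,
) -> dict[str, ArmSpec]:
    bundles = bundles if bundles is not None else reference_bundles()
    specs = {}
    for arm, models in fits.items():
        specs[arm] = ArmSpec(
            label=arm,
            os_model=models["OS"],
            aml_model=models["AML"],
            cess_model=models["CESSATION"],
            costs=bundles[arm],
            utility_mds=config.utility_mds(arm),
            utility_aml=config.utility_aml,
            single_session=config.single_session(arm),
        )
    return specs


def run_pipeline(
    config: Config,
    seed: int = 0,
    out_dir=None,
    ipd: pd.DataFrame | None = None,
    ipd_path=None,
    n_psa: int | None = None,
) -> PipelineResult:
    """Run the full analysis and (optionally) write all artifacts.

    ``ipd``/``ipd_path`` inject existing pseudo-IPD instead of simulating;
    ``n_psa`` overrides the configured draw count, with 0 skipping the
    probabilistic sensitivity analysis entirely.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    sim_seed, psa_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    manifest: dict = {
        "package": "mdscea",
        "version": __version__,
        "seed": seed,
        "stage_seeds": {"simulate": sim_seed, "psa": psa_seed},
        "config_digest": _digest(config.data),
        "config": config.data,
        "inputs": {},
        "stages": {},
        "started_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                _write_manifest(out, manifest)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {"status": "ok"}
            return result

        return deco

    @stage("simulate")
    def _ipd():
        nonlocal ipd
        if ipd_path is not None:
            p = Path(ipd_path)
            if not p.exists():
                raise FileNotFoundError(f"IPD file not found: {p}")
            manifest["inputs"]["ipd_path"] = str(p)
            manifest["inputs"]["ipd_digest"] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
            return read_ipd(p)
        if ipd is not None:
            return ipd
        scenario = config.scenario(seed=sim_seed)
        return generate_ipd(scenario)

    ipd_df = _ipd
    arms = list(dict.fromkeys(ipd_df["arm"])) if len(ipd_df) else []

    @stage("fit")
    def fits():
        return fit_endpoint_models(ipd_df, arms, criterion=config.data["selection_criterion"])

    @stage("cohort")
    def cohort():
        specs = build_arm_specs(fits, config)
        mc = config.model_config()
        traces = {arm: run_cohort(spec, mc) for arm, spec in specs.items()}
        results = {arm: accumulate(tr) for arm, tr in traces.items()}
        return specs, traces, results

    specs, traces, arm_results = cohort

    @stage("compare")
    def comparisons():
        inter = config.intervention
        comps = {
            c: incremental(arm_results[inter], arm_results[c])
            for c in config.comparators
            if c in arm_results
        }
        if len(comps) > 1:
            comps["CCR"] = weighted_comparator(
                {c: comps[c] for c in config.comparators if c in comps},
                config.weight_set(),
                mode="weight_outcomes",
            )
        return comps

    psa_result = None
    ceac_df = None
    n_draws = config.data["psa"]["n_draws"] if n_psa is None else n_psa
    if n_draws and n_draws > 0:

        @stage("psa")
        def _psa():
            arms_unc = {
                label: ArmUncertainty(
                    label=label,
                    os_model=spec.os_model,
                    aml_model=spec.aml_model,
                    cess_model=spec.cess_model,
                    costs=spec.costs,
                    utility_mds=BetaParam(spec.utility_mds),
                    cost_rel_range=config.data["psa"]["cost_rel_range"],
                    single_session=spec.single_session,
                )
                for label, spec in specs.items()
            }
            psa_spec = PSASpec(
                arms=arms_unc,
                intervention=config.intervention,
                comparators=tuple(c for c in config.comparators if c in arms_unc),
                weights=config.weight_set(),
                config=config.model_config(),
                utility_aml=BetaParam(config.utility_aml),
                aml_mortality=BetaParam(config.model_config().aml_mortality_per_cycle),
                dispersion_scale=config.data["psa"]["dispersion_scale"],
            )
            result = run_psa(psa_spec, n_draws=n_draws, rng=psa_seed)
            return result, ceac(result, config.wtp_grid())

        psa_result, ceac_df = _psa

    if out is not None:
        write_ipd(ipd_df, out / "ipd.csv")
        with open(out / "fits.json", "w") as fh:
            json.dump(
                {a: {e: m.to_dict() for e, m in ms.items()} for a, ms in fits.items()},
                fh,
                indent=2,
            )
        for arm, tr in traces.items():
            tr.to_frame().to_csv(out / f"trace_{arm}.csv", index=False, float_format="%.12g")
        write_results(comparisons, csv_path=out / "results.csv", json_path=out / "results.json")
        if psa_result is not None:
            psa_result.draws.to_csv(out / "psa_draws.csv", index=False, float_format="%.12g")
            ceac_df.to_csv(out / "ceac.csv", float_format="%.12g")
        manifest["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        _write_manifest(out, manifest)

    return PipelineResult(
        ipd=ipd_df,
        fits=fits,
        traces=traces,
        arm_results=arm_results,
        comparisons=comparisons,
        psa=psa_result,
        ceac=ceac_df,
        manifest=manifest,
    )


def _write_manifest(out, manifest) -> None:
    if out is not None:
        with open(Path(out) / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
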