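"""End-to-end orchestration: synthetic cohorts through every analysis stage.

``run_pipeline(config)`` generates a synthetic experiment from the
configured cohorts and runs deflection tracking, force calibration,
current-kinetics extraction, binned stimulus–response statistics,
pressure-clamp Boltzmann fits and calcium-response scoring, writing one
CSV per table plus a JSON report.  The run is deterministic given the
global seed, which is fanned out to per-stage child seeds by hashing the
stage name (so any single stage can be reproduced in isolation).
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import calcium as ca
from . import kinetics as kin
from . import pressure as pr
from . import response as resp
from . import synth
from .config import RunConfig
from .mechanics import deflection_to_force, spring_constant
from .tracking import Roi, fit_pillar_center, measure_deflection

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("pilarray")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tagged with the stage
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


@_stage("tracking")
def _run_tracking(config: RunConfig, n_scenes: int = 5) -> pd.DataFrame:
    rng = np.random.default_rng(synth.child_seed(config.seed, "tracking"))
    spring = spring_constant(config.calibration)
    rows = []
    for i in range(n_scenes):
        d = rng.uniform(50, 500)
        angle = rng.uniform(0, 2 * np.pi)
        spec = synth.ImageSceneSpec(
            true_deflection_nm=(d * np.cos(angle), d * np.sin(angle)),
            seed=int(rng.integers(2**31)))
        scene = synth.generate_pillar_scene(spec)
        center = scene.designated_roi_center
        half = config.detector.roi_half_width_px
        fits = {}
        for role in synth.FRAME_ROLES:
            roi = Roi.centered(center, half, scene.frames[role].shape)
            fits[role] = fit_pillar_center(scene.frames[role], roi, frame_role=role,
                                           pilus_id=scene.truth["designated_pilus"])
        meas = measure_deflection(fits["before"], fits["during"], fits["after"],
                                  spec.pixel_size_nm,
                                  recovery_limit_nm=config.detector.recovery_limit_nm)
        rows.append({
            "scene": i, "pilus_id": meas.pilus_id,
            "true_deflection_nm": scene.truth["true_deflection_magnitude_nm"],
            "measured_deflection_nm": meas.d_magnitude_nm,
            "recovery_residual_nm": meas.recovery_residual_nm,
            "force_nN": deflection_to_force(meas.d_magnitude_nm, spring),
        })
    return pd.DataFrame(rows)


@_stage("kinetics")
def _run_kinetics(config: RunConfig, n_traces: int = 20) -> pd.DataFrame:
    rng = np.random.default_rng(synth.child_seed(config.seed, "kinetics"))
    det = config.detector
    frames = []
    for group, cohort in config.cohorts.items():
        if cohort.n_cells == 0:
            continue
        phen = synth.PHENOTYPES[cohort.phenotype]
        results = []
        for _ in range(n_traces):
            spec = synth.TraceSpec(baseline_noise_sd_pA=5.0,
                                   holding_potential_mV=phen.holding_potential_mV,
                                   seed=int(rng.integers(2**31)))
            trace, _truth = synth.generate_current_trace(
                spec, phen, deflection_nm=1000.0, rng=rng, responder=True,
                threshold_nm=0.0)
            model = kin.CurrentKineticsModel(
                trace, baseline_window_ms=det.baseline_window_ms,
                k_sd=det.k_sd, sustained_ms=det.sustained_ms)
            results.append(model.fit())
        summary = kin.summarize_kinetics(results)
        summary.insert(0, "group", group)
        frames.append(summary)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


@_stage("stimulus_response")
def _run_response(config: RunConfig) -> dict:
    phenotypes = {g: synth.PHENOTYPES[c.phenotype] for g, c in config.cohorts.items()
                  if c.n_cells > 0}
    n_cells = {g: c.n_cells for g, c in config.cohorts.items() if c.n_cells > 0}
    if not phenotypes:
        return {"measurements": pd.DataFrame(), "tables": {}, "comparison": None}
    measurements, _cells = synth.generate_population(
        phenotypes, n_cells, seed=synth.child_seed(config.seed, "response"))
    tables, summaries = {}, {}
    for group, sub in measurements.groupby("group"):
        binned = resp.bin_responses(sub[["cell_id", "deflection_nm", "amplitude_pA"]],
                                    config.binning)
        tables[group] = binned
        summaries[group] = resp.summarize_cells(sub)
    comparison = None
    if len(tables) >= 2:
        (ga, gb) = sorted(tables)[:2]
        comparison = resp.compare_groups((tables[ga], summaries[ga]),
                                         (tables[gb], summaries[gb]), labels=(ga, gb))
    return {"measurements": measurements, "tables": tables,
            "summaries": summaries, "comparison": comparison}


@_stage("pressure_clamp")
def _run_hspc(config: RunConfig) -> dict:
    rng = np.random.default_rng(synth.child_seed(config.seed, "hspc"))
    fits = []
    for i in range(config.n_hspc_patches):
        fam, _ = synth.generate_pressure_family(
            config.hspc_p50_mmHg, config.hspc_slope_mmHg, config.hspc_imax_pA,
            noise_sd_pA=0.05 * config.hspc_imax_pA, rng=rng, patch_id=f"patch-{i:02d}")
        fits.append(pr.fit_boltzmann(fam))
    table = pd.DataFrame([{
        "patch_id": f.patch_id, "p50_mmHg": f.p50_mmHg, "slope_mmHg": f.slope_mmHg,
        "imax_pA": f.imax_pA, "fit_quality": f.fit_quality, "converged": f.converged,
    } for f in fits])
    return {"fits": table, "group": pr.group_p50(fits)}


@_stage("calcium")
def _run_calcium(config: RunConfig) -> pd.DataFrame:
    rng = np.random.default_rng(synth.child_seed(config.seed, "calcium"))
    traces = []
    for i in range(config.n_calcium_cells):
        baseline = rng.uniform(800, 1200)
        epochs = synth.default_calcium_epochs(
            atp_amplitude=0.8 * baseline, yoda1_amplitude=0.6 * baseline,
            gsk_amplitude=0.7 * baseline)
        trace, _ = synth.generate_fluorescence_trace(
            baseline, epochs, noise_sd=0.01 * baseline, rng=rng, cell_id=f"cell-{i:03d}")
        traces.append(trace)
    if not traces:
        return pd.DataFrame()
    return ca.score_cells(traces, threshold=config.detector.calcium_dff_threshold)


def run_pipeline(config: RunConfig, output_dir=None) -> dict:
    """Run every stage and write the report bundle.

    Returns a dict with all stage outputs; writes CSV tables and
    ``report.json`` under ``output_dir`` (default from the config).
    """
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO)

    spring = spring_constant(config.calibration)
    total_cells = sum(c.n_cells for c in config.cohorts.values())
    if total_cells == 0:
        log.warning("configuration defines zero cells: emitting empty tables")

    tracking = _run_tracking(config)
    kinetics = _run_kinetics(config)
    response = _run_response(config)
    hspc = _run_hspc(config)
    calcium_scores = _run_calcium(config)

    report = {
        "seed": config.seed,
        "config": config.to_dict(),
        "spring_constant_pN_per_nm": spring.k_pn_per_nm,
        "stage_seeds": {s: synth.child_seed(config.seed, s)
                        for s in ("tracking", "kinetics", "response", "hspc", "calcium")},
        "hspc_group_p50": hspc["group"],
    }
    comparison = response.get("comparison")
    if comparison is not None:
        means = comparison["threshold_mean_nm"]
        report["threshold_mean_nm"] = means
        report["threshold_force_nN"] = {
            g: (deflection_to_force(m, spring) if m is not None else None)
            for g, m in means.items()}
        report["responder_fisher_p"] = comparison["fisher_p"]
        report["threshold_mw_p"] = comparison["threshold_p"]

    tracking.to_csv(out / "deflection_force.csv", index=False)
    kinetics.to_csv(out / "kinetics_summary.csv", index=False)
    if response["tables"]:
        pd.concat({g: t.table() for g, t in response["tables"].items()},
                  names=["group"]).to_csv(out / "stimulus_response.csv")
    hspc["fits"].to_csv(out / "hspc_fits.csv", index=False)
    calcium_scores.to_csv(out / "calcium_scores.csv", index=False)
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    log.info("report bundle written to %s", out)

    return {"tracking": tracking, "kinetics": kinetics, "response": response,
            "hspc": hspc, "calcium": calcium_scores, "report": report}
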