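"""Reproducible end-to-end workflows over the modelling stages.

A :class:`WorkflowConfig` selects stages out of
``synth -> fit -> profile -> validate -> binding -> report`` and fixes
every knob that affects the result (generating parameters, noise level,
bounds, seeds...).  ``run_workflow`` executes the requested stages in
canonical order and writes CSV/JSON artifacts, each stamped with the
configuration hash and the seed, so any artifact is regenerable from
config + seed alone (no timestamps enter the files).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import binding as binding_mod
from .bcf import bcf_kin_structure, bcf_ss_total_model, threshold_crossing_concentration
from .binding import BindingParameters, fit_binding, scale_to_organism
from .inference import ErrorModel, FitResult, calibrate, profile_likelihood, validate
from .io import dump_json
from .model import TKParameters
from .synthetic import calibration_design, generate_binding_dataset, validation_design
from .units import DEFAULT_MOLAR_MASS, um_to_ng_per_l

__all__ = ["WorkflowConfig", "run_workflow", "report", "STAGES"]

logger = logging.getLogger("tkreceptor")

STAGES = ("synth", "fit", "profile", "validate", "binding", "report")


@dataclass
class WorkflowConfig:
    """Everything a workflow run depends on.

    The ``generating`` mapping holds the TK parameters used by the
    synthetic-data stage (defaults: the thiacloprid / G. pulex best-fit
    set); ``binding_generating`` likewise for the assay stage.
    """

    stages: tuple[str, ...] = STAGES
    outdir: str = "tkreceptor_out"
    seed: int = 1
    cv: float = 0.05
    binding_cv: float = 0.10
    generating: dict = field(
        default_factory=lambda: {"k_u": 10.6, "k_e": 5.2, "k_on": 200.0, "B_max": 25.0}
    )
    binding_generating: dict = field(
        default_factory=lambda: {"b_max": 5.7, "k_d": 0.41}
    )
    binding_levels_nm: tuple[float, ...] = (0.0, 2.5, 5.0, 10.0, 25.0)
    binding_replicates: int = 4
    mp_recovery: float = binding_mod.MP_RECOVERY
    fms: float = 0.01
    molar_mass: float = DEFAULT_MOLAR_MASS
    bounds: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=lambda: {"k_off": 0.0})
    n_starts: int = 16
    error_scale: str = "log"
    profile_params: tuple[str, ...] = ("k_u", "k_e", "B_max")
    thresholds: tuple[float, ...] = (2000.0, 5000.0)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(
                f"unknown stage(s) {unknown}; valid stages are {list(STAGES)}"
            )

    @property
    def config_hash(self) -> str:
        doc = asdict(self)
        doc.pop("outdir")  # where artifacts land does not change them
        blob = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def meta(self) -> dict:
        return {"config_hash": self.config_hash, "seed": self.seed}


def report(
    fit: FitResult,
    binding: BindingParameters | None,
    thresholds=(2000.0, 5000.0),
    mp_recovery: float = binding_mod.MP_RECOVERY,
    molar_mass: float = DEFAULT_MOLAR_MASS,
) -> dict:
    """Summary of a calibrated model, optionally next to an assay fit.

    Tabulates the best-fit parameters (with profile CIs where
    available), the whole-organism receptor capacity from both routes
    (model ``B_max * fms`` and assay ``B_max * fms / recovery``), a
    steady-state BCF-vs-concentration curve, and the water
    concentrations at which the model BCF crosses each regulatory
    threshold.
    """
    p = fit.best_fit
    doc: dict = {"fit": fit.to_dict()}
    doc["bcf_kin_structure_L_kg"] = bcf_kin_structure(p)
    doc["c_bmax_model_umol_kg"] = scale_to_organism(p.B_max, p.fms, 1.0)
    if binding is not None:
        doc["binding"] = {
            "b_max": binding.b_max,
            "k_d": binding.k_d,
            "ns": binding.ns,
            "ci_95": {k: list(v) for k, v in binding.ci_95.items()},
            "r_squared": binding.r_squared,
        }
        doc["c_bmax_assay_umol_kg"] = scale_to_organism(
            binding.b_max, p.fms, mp_recovery
        )
    grid_ng_l = np.logspace(0, 7, 57)  # 1 ng/L .. 10 mg/L
    grid_um = grid_ng_l / 1000.0 / molar_mass
    doc["bcf_curve"] = {
        "c_water_ng_L": grid_ng_l.tolist(),
        "bcf_ss_total_L_kg": [bcf_ss_total_model(p, c) for c in grid_um],
    }
    crossings = {}
    for thr in thresholds:
        c_um = threshold_crossing_concentration(p, thr)
        crossings[f"{thr:g}"] = (
            None if c_um is None else um_to_ng_per_l(c_um, molar_mass)
        )
    doc["threshold_crossings_ng_L"] = crossings
    return doc


def run_workflow(config: WorkflowConfig) -> dict[str, Path]:
    """Execute the configured stages in canonical order.

    Returns a mapping from artifact name to path.  Raises on missing
    prerequisites (e.g. ``fit`` without ``synth``) or stage failures;
    the CLI maps those onto exit codes.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGES if s in config.stages]
    meta = config.meta()
    artifacts: dict[str, Path] = {}
    logger.info("workflow stages: %s (config %s)", stages, meta["config_hash"])

    gen_params = TKParameters(fms=config.fms, **config.generating)
    error_model = ErrorModel(scale=config.error_scale)

    cal = val = fit = binding_fit = None
    if "synth" in stages:
        cal = calibration_design(
            gen_params, cv=config.cv, seed=config.seed, molar_mass=config.molar_mass
        )
        val = validation_design(
            gen_params, cv=config.cv, seed=config.seed, molar_mass=config.molar_mass
        )
        for name, ds in (("calibration", cal), ("validation", val)):
            path = outdir / f"{name}_observations.csv"
            ds.to_csv(path)
            artifacts[f"{name}_observations"] = path
        logger.info("synth: %d calibration / %d validation observations",
                    cal.n_obs, val.n_obs)

    if "fit" in stages:
        if cal is None:
            raise ValueError("'fit' requires the 'synth' stage (no dataset present)")
        fit = calibrate(
            cal,
            bounds=config.bounds or None,
            fixed=dict(config.fixed),
            seed=config.seed,
            n_starts=config.n_starts,
            error_model=error_model,
            fms=config.fms,
        )
        logger.info("fit: NLL=%.3f R2=%.4f boundary=%s",
                    fit.nll, fit.r_squared, fit.boundary_params)

    if "profile" in stages:
        if fit is None:
            raise ValueError("'profile' requires the 'fit' stage")
        frames = []
        for name in config.profile_params:
            prof = profile_likelihood(fit, cal, name)
            frames.append(prof.to_frame())
            logger.info("profile %s: CI95=%s", name, prof.ci_95)
        path = outdir / "profiles.csv"
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        artifacts["profiles"] = path

    if "validate" in stages:
        if fit is None or val is None:
            raise ValueError("'validate' requires the 'synth' and 'fit' stages")
        vrep = validate(fit, val)
        path = outdir / "validation_report.json"
        dump_json({**vrep.to_dict(), "meta": meta}, path)
        artifacts["validation_report"] = path
        logger.info("validate: R2=%.4f", vrep.r_squared)

    if "binding" in stages:
        assay = generate_binding_dataset(
            BindingParameters(**config.binding_generating),
            levels_nm=config.binding_levels_nm,
            replicates=config.binding_replicates,
            cv=config.binding_cv,
            seed=config.seed,
        )
        path = outdir / "binding_observations.csv"
        assay.to_csv(path)
        artifacts["binding_observations"] = path
        binding_fit = fit_binding(assay)
        doc = {
            "b_max": binding_fit.b_max,
            "k_d": binding_fit.k_d,
            "ci_95": {k: list(v) for k, v in binding_fit.ci_95.items()},
            "r_squared": binding_fit.r_squared,
            "c_bmax_umol_kg": scale_to_organism(
                binding_fit.b_max, config.fms, config.mp_recovery
            ),
            "meta": meta,
        }
        path = outdir / "binding_report.json"
        dump_json(doc, path)
        artifacts["binding_report"] = path
        logger.info("binding: B_max=%.3f K_d=%.3f", binding_fit.b_max, binding_fit.k_d)

    if "fit" in stages:
        path = outdir / "fit_report.json"
        dump_json({**fit.to_dict(), "meta": meta}, path)
        artifacts["fit_report"] = path

    if "report" in stages:
        if fit is None:
            raise ValueError("'report' requires the 'fit' stage")
        doc = report(
            fit,
            binding_fit,
            thresholds=config.thresholds,
            mp_recovery=config.mp_recovery,
            molar_mass=config.molar_mass,
        )
        doc["meta"] = meta
        path = outdir / "summary_report.json"
        dump_json(doc, path)
        artifacts["summary_report"] = path

    return artifacts
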