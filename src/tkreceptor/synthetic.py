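"""Synthetic exposure experiments and binding assays.

The generators emulate the designs of the *G. pulex* / thiacloprid
uptake–elimination study so that calibration, profiling and binding fits
can be exercised without any measured data:

* **I**   kinetic experiment — 2 d at 50 µg/L, 8 d depuration, sampled
  at regular intervals in duplicate;
* **II**  concentration dependence, low — 20 + 5 d at 0.05 and
  0.5 µg/L (sampled every 5 d during uptake) and 4 + 4 d at 5 µg/L;
* **III** concentration dependence, high — 2 + 2 d at 5–5000 µg/L,
  sampled at the phase ends in triplicate;
* **IV**  pulsed exposure — three cycles of 2 d exposure + 3 d
  depuration at 5 and 50 µg/L, sampled on days 1, 2, 3 and 5 of each
  cycle.

Measurement error is multiplicative lognormal with a configurable
coefficient of variation (concentrations are strictly positive and
heteroscedastic over four orders of magnitude); the noise is
median-preserving, i.e. the geometric mean of replicates converges to
the model value.  An additive-Gaussian option exists for sensitivity
checks.  Every stochastic generator takes an explicit seed and is fully
deterministic given its inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .binding import BindingDataset, BindingParameters, specific_binding
from .inference import TKDataset
from .model import ExposureScenario, TKParameters, simulate
from .units import DEFAULT_MOLAR_MASS, ug_per_l_to_um

__all__ = [
    "DesignTemplate",
    "make_scenario",
    "generate_tk_dataset",
    "generate_binding_dataset",
    "standard_templates",
    "calibration_design",
    "validation_design",
]


@dataclass(frozen=True)
class DesignTemplate:
    """One uptake–elimination experiment design.

    ``exposure_d`` / ``elimination_d`` may be scalars (shared by all
    concentration levels) or sequences aligned with
    ``concentrations_ug_l``.  ``sampling_times`` (absolute days, shared
    across levels) defaults to a design-appropriate grid: days 1, 2, 3
    and 5 within each cycle for pulsed designs, an every-5-days cadence
    for long uptake phases, and daily samples plus the phase boundaries
    otherwise.
    """

    experiment: str
    concentrations_ug_l: tuple[float, ...]
    exposure_d: float | tuple[float, ...]
    elimination_d: float | tuple[float, ...]
    pulses: int = 1
    sampling_times: tuple[float, ...] | None = None
    replicates: int = 3
    cv: float = 0.0
    seed: int | None = None
    noise: Literal["lognormal", "additive"] = "lognormal"
    molar_mass: float = DEFAULT_MOLAR_MASS

    def __post_init__(self) -> None:
        if not self.concentrations_ug_l:
            raise ValueError("template needs at least one concentration level")
        if any(c < 0 for c in self.concentrations_ug_l):
            raise ValueError("concentrations must be >= 0")
        if self.pulses < 1:
            raise ValueError(f"pulses must be >= 1, got {self.pulses}")
        for dur in (*self._per_level(self.exposure_d), *self._per_level(self.elimination_d)):
            if dur <= 0:
                raise ValueError("phase durations must be > 0")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.cv > 0 and self.seed is None:
            raise ValueError("a seed is mandatory when cv > 0")

    def _per_level(self, dur) -> tuple[float, ...]:
        if isinstance(dur, (int, float)):
            return tuple(float(dur) for _ in self.concentrations_ug_l)
        if len(dur) != len(self.concentrations_ug_l):
            raise ValueError(
                "per-level durations must match the number of concentrations"
            )
        return tuple(float(d) for d in dur)

    def durations(self, level_idx: int) -> tuple[float, float]:
        return (
            self._per_level(self.exposure_d)[level_idx],
            self._per_level(self.elimination_d)[level_idx],
        )

    def treatment_id(self, conc: float) -> str:
        return f"{self.experiment}-{conc:g}ugL"


def make_scenario(template: DesignTemplate) -> dict[str, ExposureScenario]:
    """Piecewise-constant exposure scenarios, one per concentration level."""
    scenarios = {}
    for i, conc in enumerate(template.concentrations_ug_l):
        t_up, t_elim = template.durations(i)
        scenarios[template.treatment_id(conc)] = ExposureScenario.pulses(
            ug_per_l_to_um(conc, template.molar_mass),
            t_up,
            t_elim,
            template.pulses,
            template.molar_mass,
        )
    return scenarios


def _default_sampling(t_up: float, t_elim: float, pulses: int) -> np.ndarray:
    if pulses > 1:
        period = t_up + t_elim
        offsets = [d for d in (1.0, 2.0, 3.0, 5.0) if d <= period]
        times = [p * period + d for p in range(pulses) for d in offsets]
        return np.unique(times)
    if t_up >= 10:
        uptake = np.arange(5.0, t_up + 1e-9, 5.0)
    else:
        uptake = np.arange(1.0, t_up + 1e-9, 1.0)
    uptake = np.union1d(uptake, [t_up])
    elim_offsets = [d for d in (0.5, 1.0, 2.0, 3.0, 5.0, 8.0) if d <= t_elim]
    elim = t_up + np.union1d(elim_offsets, [t_elim])
    return np.union1d(uptake, elim)


def _noise_factor(rng: np.random.Generator, cv: float, size, kind: str):
    if kind == "lognormal":
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        return np.exp(rng.normal(0.0, sigma, size))
    return 1.0 + rng.normal(0.0, cv, size)


def generate_tk_dataset(
    params: TKParameters,
    template: DesignTemplate,
    role: Literal["calibration", "validation"] = "calibration",
) -> TKDataset:
    """Simulate a design and sample noisy whole-body concentrations.

    Trajectories are simulated per concentration level, sampled at the
    template's times, and perturbed with independent multiplicative
    lognormal noise per replicate (or additive Gaussian when configured).
    Deterministic given ``(params, template)``.
    """
    scenarios = make_scenario(template)
    rng = np.random.default_rng(template.seed)
    rows = []
    for i, conc in enumerate(template.concentrations_ug_l):
        trt = template.treatment_id(conc)
        t_up, t_elim = template.durations(i)
        times = (
            np.asarray(template.sampling_times, dtype=float)
            if template.sampling_times is not None
            else _default_sampling(t_up, t_elim, template.pulses)
        )
        span = scenarios[trt].t_end
        times = times[(times > 0) & (times <= span + 1e-9)]
        traj = simulate(params, scenarios[trt], times)
        for rep in range(template.replicates):
            c_obs = traj.c_total.copy()
            if template.cv > 0:
                c_obs = c_obs * _noise_factor(
                    rng, template.cv, c_obs.shape, template.noise
                )
            rows.append(
                pd.DataFrame(
                    {
                        "time_d": times,
                        "treatment": trt,
                        "replicate": rep,
                        "c_total_umol_kg": np.clip(c_obs, 0.0, None),
                    }
                )
            )
    return TKDataset(pd.concat(rows, ignore_index=True), scenarios, role)


def generate_binding_dataset(
    params: BindingParameters,
    levels_nm: Sequence[float] = (0.0, 2.5, 5.0, 10.0, 25.0, 50.0),
    replicates: int = 4,
    cv: float = 0.0,
    seed: int | None = None,
    noise: Literal["lognormal", "additive"] = "lognormal",
) -> BindingDataset:
    """Synthetic saturation-binding assay data.

    Evaluates the one-site isotherm (plus the unspecific term when
    ``params.ns > 0``) at each free-concentration level and applies
    multiplicative noise per replicate.  The default levels are the
    in vitro assay series (0–50 nM).
    """
    levels = np.asarray(levels_nm, dtype=float)
    if np.any(levels < 0):
        raise ValueError("levels must be >= 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv > 0 and seed is None:
        raise ValueError("a seed is mandatory when cv > 0")
    rng = np.random.default_rng(seed)
    truth = specific_binding(levels, params)
    rows = []
    for rep in range(int(replicates)):
        bound = truth.copy()
        if cv > 0:
            bound = bound * _noise_factor(rng, cv, bound.shape, noise)
        rows.append(
            pd.DataFrame(
                {
                    "c_free_nM": levels,
                    "c_bound_umol_kgMP": np.clip(bound, 0.0, None),
                    "replicate": rep,
                }
            )
        )
    return BindingDataset(pd.concat(rows, ignore_index=True))


# ----------------------------------------------------------------------
# study-design templates
# ----------------------------------------------------------------------

def standard_templates(
    cv: float = 0.0, seed: int | None = None, molar_mass: float = DEFAULT_MOLAR_MASS
) -> dict[str, DesignTemplate]:
    """The four uptake–elimination designs of the study, keyed I–IV."""
    common = dict(cv=cv, molar_mass=molar_mass)
    seeds = (
        {k: None for k in "I II III IV".split()}
        if seed is None
        else dict(zip("I II III IV".split(), np.random.SeedSequence(seed).generate_state(4) % (2**31)))
    )
    return {
        "I": DesignTemplate(
            experiment="I",
            concentrations_ug_l=(50.0,),
            exposure_d=2.0,
            elimination_d=8.0,
            replicates=2,
            seed=seeds["I"],
            **common,
        ),
        "II": DesignTemplate(
            experiment="II",
            concentrations_ug_l=(0.05, 0.5, 5.0),
            exposure_d=(20.0, 20.0, 4.0),
            elimination_d=(5.0, 5.0, 4.0),
            replicates=3,
            seed=seeds["II"],
            **common,
        ),
        "III": DesignTemplate(
            experiment="III",
            concentrations_ug_l=(5.0, 50.0, 500.0, 1500.0, 5000.0),
            exposure_d=2.0,
            elimination_d=2.0,
            sampling_times=(1.0, 2.0, 3.0, 4.0),
            replicates=3,
            seed=seeds["III"],
            **common,
        ),
        "IV": DesignTemplate(
            experiment="IV",
            concentrations_ug_l=(5.0, 50.0),
            exposure_d=2.0,
            elimination_d=3.0,
            pulses=3,
            replicates=3,
            seed=seeds["IV"],
            **common,
        ),
    }


def calibration_design(
    params: TKParameters,
    cv: float = 0.0,
    seed: int | None = None,
    molar_mass: float = DEFAULT_MOLAR_MASS,
) -> TKDataset:
    """Synthetic calibration dataset over constant exposures.

    Uses the five constant-exposure calibration treatments (0.05, 0.5,
    5, 50 and 1500 µg/L), drawing each from the design it belongs to:
    the low and mid concentrations from the concentration-dependence
    experiments and 50 µg/L from the kinetic experiment.
    """
    t = standard_templates(cv=cv, seed=seed, molar_mass=molar_mass)
    arm_ii = t["II"]
    arm_iii = replace(
        t["III"], concentrations_ug_l=(1500.0,), sampling_times=(1.0, 2.0, 3.0, 4.0)
    )
    ds = generate_tk_dataset(params, t["I"], role="calibration")
    ds = ds.concat(generate_tk_dataset(params, arm_ii, role="calibration"))
    ds = ds.concat(generate_tk_dataset(params, arm_iii, role="calibration"))
    ds.role = "calibration"
    return ds


def validation_design(
    params: TKParameters,
    cv: float = 0.0,
    seed: int | None = None,
    molar_mass: float = DEFAULT_MOLAR_MASS,
) -> TKDataset:
    """Synthetic validation dataset: constant (5–5000 µg/L) and pulsed
    (5 and 50 µg/L) exposures, predicted but never fitted."""
    t = standard_templates(cv=cv, seed=None if seed is None else seed + 1, molar_mass=molar_mass)
    arm_iii = replace(t["III"], concentrations_ug_l=(5.0, 50.0, 500.0, 5000.0))
    ds = generate_tk_dataset(params, arm_iii, role="validation")
    ds = ds.concat(generate_tk_dataset(params, t["IV"], role="validation"))
    ds.role = "validation"
    return ds
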