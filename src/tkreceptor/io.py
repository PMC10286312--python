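"""Reading and writing of scenario, parameter and report files.

Scenario files are YAML/JSON mappings with a mandatory concentration
unit tag::

    unit: ug_per_L          # or: uM
    molar_mass: 250.0       # g/mol, used for ug_per_L -> uM conversion
    intervals:
      - {start: 0, end: 2, concentration: 50}
      - {start: 2, end: 10, concentration: 0}

Observation tables are CSV with columns ``time_d, treatment, replicate,
c_total_umol_kg``; binding-assay tables use ``c_free_nM,
c_bound_umol_kgMP, replicate``.  Reports are JSON with deterministic
key order so that identical configurations yield byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .model import ExposureScenario, TKParameters
from .units import DEFAULT_MOLAR_MASS, ug_per_l_to_um, um_to_ug_per_l

__all__ = [
    "load_scenario",
    "dump_scenario",
    "load_parameters",
    "dump_json",
]


def load_scenario(path) -> ExposureScenario:
    """Load an exposure scenario from a YAML/JSON file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return scenario_from_dict(doc)


def scenario_from_dict(doc: dict) -> ExposureScenario:
    unit = doc.get("unit")
    if unit not in ("uM", "ug_per_L"):
        raise ValueError(
            f"scenario must carry a unit tag 'uM' or 'ug_per_L', got {unit!r}"
        )
    molar_mass = float(doc.get("molar_mass", DEFAULT_MOLAR_MASS))
    intervals = []
    for iv in doc["intervals"]:
        c = float(iv["concentration"])
        if unit == "ug_per_L":
            c = ug_per_l_to_um(c, molar_mass)
        intervals.append((float(iv["start"]), float(iv["end"]), c))
    return ExposureScenario(tuple(intervals), molar_mass)


def dump_scenario(scenario: ExposureScenario, path, unit: str = "uM") -> None:
    if unit not in ("uM", "ug_per_L"):
        raise ValueError(f"unknown unit {unit!r}")
    intervals = []
    for a, b, c in scenario.intervals:
        if unit == "ug_per_L":
            c = um_to_ug_per_l(c, scenario.molar_mass)
        intervals.append({"start": a, "end": b, "concentration": c})
    doc = {"unit": unit, "molar_mass": scenario.molar_mass, "intervals": intervals}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_parameters(path) -> TKParameters:
    """Load TK parameters from a YAML/JSON mapping of field names."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    known = {"k_u", "k_e", "k_on", "B_max", "k_off", "fms"}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown parameter field(s): {sorted(unknown)}")
    return TKParameters(**{k: float(v) for k, v in doc.items()})


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def dump_json(doc: dict, path) -> None:
    """Write a report dict as deterministic, human-readable JSON."""
    Path(path).write_text(json.dumps(_jsonable(doc), indent=2, sort_keys=True) + "\n")
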