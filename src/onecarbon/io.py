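"""Configuration and result I/O.

Parameter sets travel as structured YAML: one entry per kinetic
constant, keyed ``reaction.constant``, carrying the numeric value, its
unit and a source annotation (printed rate law, literature value of the
model family, or back-solved calibration).  Loading validates every
key, every unit and every positivity constraint; unknown keys are
rejected so configs cannot silently drift from the model.

Steady-state and sweep results are written as tidy delimited tables
with a YAML sidecar run record (scenario spec, parameter checksum,
solver settings, software version, timestamp).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .dynamics import DEFAULT_TOL, SteadyStateResult
from .experiments import SweepResult
from .model import KineticParameters, RegulationSwitches
from .scenarios import ScenarioSpec

__all__ = [
    "RunRecord",
    "parameter_checksum",
    "save_config",
    "load_config",
    "write_results",
    "results_frame",
    "default_config_path",
]


def default_config_path() -> Path:
    """Path of the shipped, fully annotated male baseline config."""
    return Path(__file__).parent / "data" / "male_default.yaml"


def _unit_for(field_name: str) -> str:
    if field_name.endswith(("_vmax", "_vmax_f", "_vmax_r")) or field_name.endswith("_input"):
        return "uM/h"
    if field_name.endswith("_use_k"):
        return "1/h"
    if field_name == "ne_k1":
        return "1/(uM*h)"
    if field_name == "ne_k2":
        return "1/h"
    if field_name in ("bhmt_inh_coeff", "mat1_inh_coeff"):
        return "1/uM"
    if field_name in ("pemt_pe_prefactor", "mat3_hill", "gnmt_hill",
                      "bhmt_act_slope", "cbs_act_amp", "cbs_bet_amp",
                      "mat1_inh_base", "mat1_inh_amp", "mat3_act_amp",
                      "bet_use_vmax"):
        return "uM/h" if field_name == "bet_use_vmax" else "dimensionless"
    return "uM"


#: Source annotation per constant: "printed" = stated in the Methods
#: rate laws; "family" = literature value of this hepatic-OCM model
#: family; "calibrated" = back-solved from the male reference steady
#: state / printed tables.
_PRINTED = {
    "pemt_vmax", "pemt_km_sam", "pemt_ki_sah", "pemt_km_pe", "pemt_pe_prefactor",
    "sms_vmax", "sms_km", "phld_vmax", "phld_km", "chox_vmax", "chox_km",
    "bah_vmax", "bah_km",
    "bhmt_km_hcy", "bhmt_km_bet", "bhmt_inh_coeff", "bhmt_ref_samsah",
    "bhmt_act_slope", "bhmt_ref_bet",
    "cbs_km_hcy", "cbs_act_amp", "cbs_act_k", "cbs_ref_samsah",
    "cbs_bet_amp", "cbs_bet_k", "cbs_ref_bet",
}
_CALIBRATED_SUFFIXES = ("_vmax", "_vmax_f", "_vmax_r")
_CALIBRATED_EXTRA = {
    "pe", "sphmy", "met_input", "folate_total", "bet_input",
    "chol_use_k", "bet_use_vmax", "bet_use_km", "ser_input", "ser_use_k",
    "gly_use_k", "sarc_use_k", "ne_k2",
}


def _source_for(field_name: str) -> str:
    if field_name in _PRINTED:
        return "printed rate law"
    if field_name.endswith(_CALIBRATED_SUFFIXES) or field_name in _CALIBRATED_EXTRA:
        return "calibrated (male reference steady state)"
    return "model-family literature value"


def parameter_checksum(p: KineticParameters,
                       sw: RegulationSwitches | None = None) -> str:
    """Deterministic checksum of a full parameterization."""
    payload = {f.name: repr(getattr(p, f.name)) for f in dataclasses.fields(p)}
    if sw is not None:
        payload.update({f.name: getattr(sw, f.name) for f in dataclasses.fields(sw)})
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclasses.dataclass
class RunRecord:
    """Provenance sidecar for a written result table."""

    scenario: dict
    parameter_checksum: str
    solver: dict
    result_path: str
    software_version: str
    timestamp: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def save_config(path: str | Path, p: KineticParameters,
                sw: RegulationSwitches | None = None,
                spec: ScenarioSpec | None = None) -> Path:
    """Write a fully annotated parameter/switch/scenario config."""
    path = Path(path)
    doc: dict = {"parameters": {}}
    for f in dataclasses.fields(p):
        key = f.name.replace("_", ".", 1)
        doc["parameters"][key] = {
            "value": float(getattr(p, f.name)),
            "unit": _unit_for(f.name),
            "source": _source_for(f.name),
        }
    if sw is not None:
        doc["switches"] = {f.name: bool(getattr(sw, f.name))
                           for f in dataclasses.fields(sw)}
    if spec is not None:
        doc["scenario"] = spec.to_dict()
    doc["checksum"] = parameter_checksum(p, sw)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
    return path


def load_config(path: str | Path) -> tuple[KineticParameters,
                                           RegulationSwitches,
                                           ScenarioSpec]:
    """Load and validate a config written by :func:`save_config`.

    Unknown parameter keys, unit mismatches and constraint violations
    raise ``ValueError``/``KeyError`` naming the offending key.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "parameters" not in doc:
        raise ValueError(f"{path}: not a parameter config (missing 'parameters')")

    known = {f.name for f in dataclasses.fields(KineticParameters)}
    values: dict[str, float] = {}
    for key, entry in doc["parameters"].items():
        name = key.replace(".", "_", 1)
        if name not in known:
            raise KeyError(f"{path}: unknown parameter key {key!r}")
        if not isinstance(entry, dict) or "value" not in entry:
            raise ValueError(f"{path}: parameter {key!r} must carry a 'value'")
        unit = entry.get("unit")
        expected = _unit_for(name)
        if unit is not None and unit != expected:
            raise ValueError(
                f"{path}: parameter {key!r} has unit {unit!r}, expected {expected!r}"
            )
        values[name] = float(entry["value"])
    missing = known - set(values)
    if missing:
        raise ValueError(f"{path}: missing parameters {sorted(missing)}")
    p = KineticParameters(**values)  # dataclass validation applies here

    sw_doc = doc.get("switches", {})
    known_sw = {f.name for f in dataclasses.fields(RegulationSwitches)}
    unknown_sw = set(sw_doc) - known_sw
    if unknown_sw:
        raise KeyError(f"{path}: unknown switch keys {sorted(unknown_sw)}")
    sw = RegulationSwitches(**{k: bool(v) for k, v in sw_doc.items()})

    spec = ScenarioSpec.from_dict(doc.get("scenario") or {})
    return p, sw, spec


def results_frame(result: SteadyStateResult, scenario_id: str = "run") -> pd.DataFrame:
    """Tidy one-row-per-quantity table for a steady-state result."""
    rows = []
    for name, value in result.state.as_dict().items():
        rows.append({"name": name, "kind": "concentration",
                     "value": value, "unit": "uM", "scenario": scenario_id})
    for name, value in result.fluxes.items():
        rows.append({"name": name, "kind": "flux",
                     "value": value, "unit": "uM/h", "scenario": scenario_id})
    for name, value in [("transmethylation", result.transmethylation),
                        ("remethylation", result.remethylation),
                        ("transsulfuration", result.transsulfuration)]:
        rows.append({"name": name, "kind": "derived_flux",
                     "value": value, "unit": "uM/h", "scenario": scenario_id})
    return pd.DataFrame.from_records(rows)


def write_results(obj, path: str | Path, fmt: str = "csv",
                  p: KineticParameters | None = None,
                  sw: RegulationSwitches | None = None,
                  spec: ScenarioSpec | None = None,
                  scenario_id: str = "run",
                  tol: float = DEFAULT_TOL) -> Path:
    """Write a result/sweep/table as a delimited file plus a sidecar
    run record (``<path>.run.yaml``).

    ``obj`` may be a :class:`SteadyStateResult`, a
    :class:`~onecarbon.experiments.SweepResult` or a plain DataFrame.
    Column order is deterministic; re-running with the same config
    produces byte-identical tables.
    """
    path = Path(path)
    if fmt not in ("csv", "tsv"):
        raise ValueError("fmt must be 'csv' or 'tsv'")
    sep = "," if fmt == "csv" else "\t"

    if isinstance(obj, SteadyStateResult):
        df = results_frame(obj, scenario_id)
        scenario = spec.to_dict() if spec else {}
    elif isinstance(obj, SweepResult):
        df = obj.table
        scenario = {"sweep": obj.provenance}
    elif isinstance(obj, pd.DataFrame):
        df = obj
        scenario = spec.to_dict() if spec else {}
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")

    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=isinstance(df.index, pd.Index)
              and df.index.name is not None, float_format="%.10g")

    record = RunRecord(
        scenario=scenario,
        parameter_checksum=parameter_checksum(p, sw) if p is not None else "",
        solver={"tol": tol, "method": "BDF + Newton polish"},
        result_path=str(path),
        software_version=_version(),
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    with open(path.with_suffix(path.suffix + ".run.yaml"), "w") as fh:
        yaml.safe_dump(record.to_dict(), fh, sort_keys=True)
    return path


def _version() -> str:
    from . import __version__
    return __version__
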