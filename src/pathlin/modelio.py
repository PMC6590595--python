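"""Serialization of model specs, steady states, linear models and reports.

Model specs are JSON (or YAML) documents::

    {
      "name": "...",
      "species": ["A", "B", "C"],
      "reactions": [{"reactants": {"A": 1, "B": 1},
                     "products": {"C": 1},
                     "rate_param": "k_bind"}],
      "parameters": {"k_bind": 1.0},
      "inputs": {"uA": "A", "uB": "B"},
      "readouts": ["C"]
    }

Reading and writing round-trip exactly (dict order is preserved — the
order of ``inputs`` defines the layout of the input vector).  Reports
serialize to JSON or to a CSV whose rows are one (workflow, r_noise,
scope) combination with the std-ratio, MRE and MSE columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .accuracy import MCReport
from .errors import ConfigurationError, ModelValidationError
from .linearization import LinearModel
from .reaction_model import ReactionNetwork
from .simulation import SteadyState

__all__ = [
    "read_model",
    "write_model",
    "read_input_vector",
    "write_steady_state",
    "read_steady_state",
    "write_linear_model",
    "read_linear_model",
    "write_report",
    "read_report_csv",
    "round_floats",
]

_REQUIRED_KEYS = ("species", "reactions", "parameters", "inputs")

#: significant digits used when serializing floats
FLOAT_DIGITS = 12


def round_floats(obj):
    """Recursively round floats to FLOAT_DIGITS significant digits."""
    if isinstance(obj, float):
        return float(f"{obj:.{FLOAT_DIGITS}g}")
    if isinstance(obj, dict):
        return {k: round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [round_floats(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return round_floats(obj.tolist())
    if isinstance(obj, (np.floating,)):
        return round_floats(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _load_document(path: Path) -> dict:
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _dump_document(doc: dict, path: Path) -> None:
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2, sort_keys=False) + "\n")


def read_model(path) -> ReactionNetwork:
    """Parse a model spec file (JSON or YAML) into a network."""
    path = Path(path)
    doc = _load_document(path)
    if not isinstance(doc, dict):
        raise ModelValidationError(f"{path}: model spec must be a mapping")
    for key in _REQUIRED_KEYS:
        if key not in doc:
            raise ModelValidationError(f"{path}: missing required field '{key}'")
    for j, rxn in enumerate(doc["reactions"]):
        for key in ("reactants", "products", "rate_param"):
            if key not in rxn:
                raise ModelValidationError(
                    f"{path}: reactions[{j}] missing field '{key}'"
                )
    return ReactionNetwork(
        species=doc["species"],
        reactions=doc["reactions"],
        parameters=doc["parameters"],
        inputs=doc["inputs"],
        readouts=doc.get("readouts", []),
        name=doc.get("name", path.stem),
    )


def write_model(network: ReactionNetwork, path) -> None:
    """Write a model spec; write_model(read_model(p)) is content-identical."""
    _dump_document(network.as_dict(), Path(path))


def read_input_vector(path, network: ReactionNetwork) -> np.ndarray:
    """Read an input vector: either a list or a {input_name: value} map."""
    doc = _load_document(Path(path))
    if isinstance(doc, dict):
        missing = [k for k in network.inputs if k not in doc]
        if missing:
            raise ConfigurationError(f"input file missing entries for {missing}")
        return np.asarray([float(doc[k]) for k in network.inputs])
    u = np.asarray(doc, dtype=float)
    if u.shape != (network.n_inputs,):
        raise ConfigurationError(
            f"input vector has {u.shape} entries, expected {network.n_inputs}"
        )
    return u


def write_steady_state(ss: SteadyState, path) -> None:
    doc = round_floats(
        {
            "x_ss": ss.x_ss,
            "u_bf": ss.u_bf,
            "residual_norm": ss.residual_norm,
            "t_converged": ss.t_converged,
            "method": ss.method,
        }
    )
    _dump_document(doc, Path(path))


def read_steady_state(path) -> SteadyState:
    doc = _load_document(Path(path))
    return SteadyState(
        x_ss=np.asarray(doc["x_ss"], dtype=float),
        u_bf=np.asarray(doc["u_bf"], dtype=float),
        residual_norm=float(doc["residual_norm"]),
        t_converged=float(doc["t_converged"]),
        method=doc.get("method", "integrate+newton"),
    )


def write_linear_model(lin: LinearModel, path) -> None:
    eig = lin.eigenvalues
    doc = round_floats(
        {
            "A": lin.A,
            "B": lin.B,
            "x_ss": lin.x_ss,
            "u_bf": lin.u_bf,
            "eigenvalues_re": eig.real,
            "eigenvalues_im": eig.imag,
        }
    )
    _dump_document(doc, Path(path))


def read_linear_model(path) -> LinearModel:
    doc = _load_document(Path(path))
    return LinearModel(
        A=np.asarray(doc["A"], dtype=float),
        B=np.asarray(doc["B"], dtype=float),
        x_ss=np.asarray(doc["x_ss"], dtype=float),
        u_bf=np.asarray(doc["u_bf"], dtype=float),
    )


_REPORT_COLUMNS = ["workflow_id", "r_noise", "scope", "std_ratio_pct", "MRE_pct", "MSE"]


def _report_frame(reports) -> pd.DataFrame:
    if isinstance(reports, MCReport):
        reports = [reports]
    rows = []
    for rep in reports:
        for _, r in rep.table.iterrows():
            rows.append(
                {
                    "workflow_id": rep.workflow_id,
                    "r_noise": r.r_noise,
                    "scope": r.scope,
                    "std_ratio_pct": r.std_ratio_pct,
                    "MRE_pct": r.mre_pct,
                    "MSE": r.mse,
                }
            )
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)


def write_report(reports, path, format: str | None = None) -> pd.DataFrame:
    """Write one or many workflow reports as JSON or CSV.

    JSON keeps run metadata (seeds, sample counts, exclusions) next to the
    rows; CSV holds only the metric rows.  Floats are written with
    FLOAT_DIGITS significant digits so identical runs produce identical
    files.  Returns the flat row table.
    """
    path = Path(path)
    fmt = format or (path.suffix.lstrip(".") or "json")
    frame = _report_frame(reports)
    if fmt == "csv":
        frame.to_csv(path, index=False, float_format=f"%.{FLOAT_DIGITS}g")
    elif fmt == "json":
        reps = [reports] if isinstance(reports, MCReport) else list(reports)
        doc = {
            "meta": [
                {
                    "workflow_id": rep.workflow_id,
                    "model_id": rep.model_id,
                    "seed": rep.seed,
                    "n_samples": rep.n_samples,
                    "n_excluded_samples": rep.n_excluded_samples,
                }
                for rep in reps
            ],
            "rows": round_floats(frame.to_dict(orient="records")),
        }
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    else:
        raise ConfigurationError(f"unknown report format '{fmt}'")
    return frame


def read_report_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
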