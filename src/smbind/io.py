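"""Plain-text readers and writers for traces, truth records, idealizations,
model catalogs and fit results. All formats are auditable text: delimited
columns, JSON and YAML; no binary containers."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .models import ConstraintSet, KineticModel, State, Transition
from .simulate import FluorescenceTrace, TruthRecord


class ParseError(ValueError):
    """Malformed input file, with file and line context."""


def write_trace(path: str | Path, trace: FluorescenceTrace) -> None:
    """Two-column delimited text: time_s, intensity_au."""
    data = np.column_stack([trace.time_s, trace.intensity])
    header = "time_s\tintensity_au"
    np.savetxt(path, data, fmt="%.17g", delimiter="\t", header=header, comments="")


def read_trace(
    path: str | Path,
    concentration_nM: float | None = None,
    molecule_id: str | None = None,
) -> FluorescenceTrace:
    path = Path(path)
    try:
        data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: malformed trace file ({exc})") from exc
    if data.shape[1] != 2:
        raise ParseError(f"{path}: expected 2 columns, found {data.shape[1]}")
    if data.shape[0] < 2:
        raise ParseError(f"{path}: need at least 2 frames to infer the frame interval")
    dt = float(np.median(np.diff(data[:, 0])))
    return FluorescenceTrace(
        intensity=data[:, 1], frame_interval_s=dt,
        concentration_nM=concentration_nM, molecule_id=molecule_id,
    )


def write_truth(path: str | Path, truth: TruthRecord) -> None:
    payload = {
        "n_sites": int(truth.site_occupancy.shape[0]),
        "n_frames": int(truth.site_occupancy.shape[1]),
        "events": [
            {"site": s, "start_frame": a, "end_frame": b, "amplitude": amp}
            for s, a, b, amp in truth.events
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> TruthRecord:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
        occ = np.zeros((payload["n_sites"], payload["n_frames"]), dtype=bool)
        events = []
        for e in payload["events"]:
            occ[e["site"], e["start_frame"]:e["end_frame"]] = True
            events.append((e["site"], e["start_frame"], e["end_frame"], e["amplitude"]))
    except (json.JSONDecodeError, KeyError, IndexError) as exc:
        raise ParseError(f"{path}: malformed truth file ({exc})") from exc
    return TruthRecord(site_occupancy=occ, events=events)


def write_idealized(path: str | Path, counts: np.ndarray) -> None:
    """Two-column delimited text: frame, bound count."""
    data = np.column_stack([np.arange(len(counts)), counts])
    np.savetxt(path, data, fmt="%d", delimiter="\t", header="frame\tcount", comments="")


def read_idealized(path: str | Path) -> np.ndarray:
    path = Path(path)
    try:
        data = np.loadtxt(path, delimiter="\t", skiprows=1, dtype=np.int64, ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: malformed idealized file ({exc})") from exc
    return data[:, 1]


def model_to_dict(model: KineticModel, constraints: ConstraintSet) -> dict:
    return {
        "name": model.name,
        "states": [
            {"label": s.label, "ligation": s.ligation, "conformation": s.conformation}
            for s in model.states
        ],
        "transitions": [
            {"from": t.frm, "to": t.to, "param": t.param,
             "multiplier": t.multiplier, "conc_exponent": t.conc_exponent}
            for t in model.transitions
        ],
        "constraints": {
            "fixed": dict(constraints.fixed),
            "ties": {
                name: {"coef": coef, "bases": [[b, e] for b, e in bases]}
                for name, (coef, bases) in constraints.ties.items()
            },
        },
    }


def dict_to_model(payload: dict) -> tuple[KineticModel, ConstraintSet]:
    try:
        model = KineticModel(
            name=payload["name"],
            states=tuple(
                State(s["label"], s["ligation"], s.get("conformation", ""))
                for s in payload["states"]
            ),
            transitions=tuple(
                Transition(t["from"], t["to"], t["param"],
                           t.get("multiplier", 1.0), t.get("conc_exponent", 0))
                for t in payload["transitions"]
            ),
        )
        c = payload.get("constraints", {})
        constraints = ConstraintSet(
            fixed=dict(c.get("fixed", {})),
            ties={
                name: (tie["coef"], tuple((b, e) for b, e in tie["bases"]))
                for name, tie in c.get("ties", {}).items()
            },
        )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed model definition ({exc})") from exc
    constraints.validate(model)
    return model, constraints


def write_model_yaml(path: str | Path, model: KineticModel, constraints: ConstraintSet) -> None:
    Path(path).write_text(yaml.safe_dump(model_to_dict(model, constraints), sort_keys=False))


def read_model_yaml(path: str | Path) -> tuple[KineticModel, ConstraintSet]:
    path = Path(path)
    try:
        payload = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: malformed YAML ({exc})") from exc
    if not isinstance(payload, dict):
        raise ParseError(f"{path}: expected a mapping at top level")
    return dict_to_model(payload)


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, default=_json_default))


def read_json(path: str | Path) -> dict:
    path = Path(path)
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: malformed JSON ({exc})") from exc


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
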