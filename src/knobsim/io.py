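"""Reading and writing the package's text formats.

Everything is plain text: model/protocol files and session configs are
YAML, traces are CSV with a JSON sidecar carrying the exact parameter set
and protocol that produced them (so a trace file round-trips back into a
re-runnable configuration).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .controller import DeviceLayout, ParameterBinding, uc33_layout
from .model import HHParameters, SimulationTrace, StimulusProtocol
from .session import SessionConfig, default_bindings

__all__ = [
    "load_model_file",
    "save_model_file",
    "write_trace",
    "read_trace",
    "load_session_config",
    "save_session_config",
]

TRACE_HEADER = "t_ms,V_mV,m,h,n"


def load_model_file(path) -> tuple:
    """Read a parameter/protocol YAML file -> (HHParameters, StimulusProtocol).

    Either section may be omitted; missing keys fall back to defaults.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    params = HHParameters(**doc.get("parameters", {}))
    proto = StimulusProtocol(**doc.get("protocol", {}))
    return params, proto


def save_model_file(params: HHParameters, proto: StimulusProtocol, path) -> None:
    doc = {"parameters": params.to_dict(), "protocol": proto.to_dict()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_trace(trace: SimulationTrace, csv_path,
                params: HHParameters | None = None,
                proto: StimulusProtocol | None = None) -> None:
    """Write a trace as CSV plus a ``<name>.json`` sidecar with the full
    parameter set, protocol and spike times."""
    csv_path = Path(csv_path)
    data = np.column_stack([trace.t, trace.V, trace.m, trace.h, trace.n])
    np.savetxt(csv_path, data, delimiter=",", header=TRACE_HEADER, comments="")
    sidecar = {
        "spike_times_ms": list(trace.spike_times),
        "clamp_hits": trace.clamp_hits,
    }
    if params is not None:
        sidecar["parameters"] = params.to_dict()
    if proto is not None:
        sidecar["protocol"] = proto.to_dict()
    with open(csv_path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_trace(csv_path) -> SimulationTrace:
    data = np.loadtxt(csv_path, delimiter=",", skiprows=1)
    trace = SimulationTrace(t=data[:, 0], V=data[:, 1], m=data[:, 2],
                            h=data[:, 3], n=data[:, 4])
    sidecar = Path(csv_path).with_suffix(".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        trace.spike_times = list(meta.get("spike_times_ms", []))
        trace.clamp_hits = int(meta.get("clamp_hits", 0))
    return trace


def _parse_bindings(entries) -> list:
    if entries in (None, "default"):
        return default_bindings()
    return [ParameterBinding(**e) for e in entries]


def load_session_config(path) -> SessionConfig:
    """Read a session YAML file.

    Recognised keys: ``parameters``, ``protocol``, ``backend``,
    ``coalesce``, ``output_dir``, ``bindings`` (list of binding mappings or
    the string ``default``), ``banks`` (name -> binding list) and
    ``bank_buttons`` (button element id -> bank name).  The device layout
    is currently always the bundled UC-33 emulation.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    layout_name = doc.get("layout", "uc33")
    if layout_name != "uc33":
        raise ValueError(f"unknown layout {layout_name!r}; available: uc33")
    return SessionConfig(
        layout=uc33_layout(),
        bindings=_parse_bindings(doc.get("bindings", "default")),
        parameters=HHParameters(**doc.get("parameters", {})),
        protocol=StimulusProtocol(**doc.get("protocol", {})),
        backend_spec=doc.get("backend", "virtual:"),
        output_dir=doc.get("output_dir"),
        coalesce=bool(doc.get("coalesce", False)),
        banks={name: _parse_bindings(bl) for name, bl in doc.get("banks", {}).items()},
        bank_buttons={int(k): v for k, v in doc.get("bank_buttons", {}).items()},
    )


def _binding_to_dict(b: ParameterBinding) -> dict:
    d = {"element_id": b.element_id, "parameter": b.parameter,
         "map_kind": b.map_kind, "low": b.low, "high": b.high}
    if b.meta_low_id is not None:
        d["meta_low_id"] = b.meta_low_id
    if b.meta_high_id is not None:
        d["meta_high_id"] = b.meta_high_id
    return d


def save_session_config(config: SessionConfig, path) -> None:
    doc = {
        "layout": "uc33",
        "backend": config.backend_spec,
        "coalesce": config.coalesce,
        "parameters": config.parameters.to_dict(),
        "protocol": config.protocol.to_dict(),
        "bindings": [_binding_to_dict(b) for b in config.bindings],
    }
    if config.banks:
        doc["banks"] = {name: [_binding_to_dict(b) for b in bl]
                        for name, bl in config.banks.items()}
    if config.bank_buttons:
        doc["bank_buttons"] = dict(config.bank_buttons)
    if config.output_dir:
        doc["output_dir"] = config.output_dir
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
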