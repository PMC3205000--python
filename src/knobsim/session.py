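"""The closed loop: poll controller events, apply bindings, re-simulate, log.

A session starts from a full parameter snapshot, runs one baseline
simulation, then consumes controller events.  Every applied event (a bound
primary element or a meta element) bumps the *simulation index* — the
ordinal count of model reruns — reruns the model, and appends one
:class:`TrajectoryRecord`.  The resulting :class:`SessionLog` is a complete,
self-contained account: replaying its records from the initial snapshot
reproduces the final parameter set exactly and the final voltage trace
bit-for-bit, which is what makes hand-tuned parameter journeys regression-
testable.

Buttons can switch *binding banks*: a session config may define several
binding tables and assign buttons that swap the active one on press
(raw value 127).
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import dataclass, field, asdict

from . import controller as ctl
from .controller import ParameterBinding, DeviceLayout, uc33_layout
from .model import (
    HHParameters,
    StimulusProtocol,
    SimulationTrace,
    TUNABLE_PARAMETERS,
    PARAMETER_UNITS,
    simulate,
)

__all__ = [
    "SessionConfig",
    "TrajectoryRecord",
    "SessionLog",
    "SessionResult",
    "default_bindings",
    "run_session",
    "replay",
    "plot_trajectories",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

logger = logging.getLogger(__name__)

LOG_FORMAT_VERSION = 1

#: Parameters a binding may target: the eleven kinetics/conductance knobs
#: plus the stimulus amplitude.
BINDABLE_PARAMETERS = TUNABLE_PARAMETERS + ("I_amp",)


def default_bindings() -> list:
    """The stock 12-element HH session: eleven model parameters plus the
    injected current amplitude, on elements 0-11 of the UC-33 layout.

    Time constants and conductances get exponential mappings (they span
    orders of magnitude); voltages and slopes are linear.
    """
    spec = [
        ("tau_m", "exponential", 0.05, 10.0),
        ("tau_h", "exponential", 0.5, 50.0),
        ("tau_n", "exponential", 0.5, 50.0),
        ("mu_m", "linear", -60.0, -20.0),
        ("mu_h", "linear", -90.0, -40.0),
        ("mu_n", "linear", -80.0, -30.0),
        ("s_m", "linear", 1.0, 20.0),
        ("s_h", "linear", -20.0, -1.0),
        ("s_n", "linear", 1.0, 25.0),
        ("gNa_max", "exponential", 1.0, 300.0),
        ("gK_max", "exponential", 1.0, 200.0),
        ("I_amp", "linear", 0.0, 30.0),
    ]
    return [
        ParameterBinding(element_id=i, parameter=name, map_kind=kind, low=lo, high=hi)
        for i, (name, kind, lo, hi) in enumerate(spec)
    ]


class ConfigError(ValueError):
    """Session configuration is internally inconsistent."""


@dataclass
class SessionConfig:
    """Everything a session needs: device, bindings, model, protocol, backend."""

    layout: DeviceLayout = field(default_factory=uc33_layout)
    bindings: list = field(default_factory=default_bindings)
    parameters: HHParameters = field(default_factory=HHParameters)
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    backend_spec: str = "virtual:"
    output_dir: str | None = None
    coalesce: bool = False
    #: optional named alternative binding tables
    banks: dict = field(default_factory=dict)
    #: button element_id -> bank name ("" or "default" = primary table)
    bank_buttons: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        tables = [("default", self.bindings)] + list(self.banks.items())
        for bank_name, bindings in tables:
            seen = set()
            for b in bindings:
                if b.element_id not in self.layout:
                    raise ConfigError(
                        f"bank {bank_name!r}: element {b.element_id} not in layout "
                        f"{self.layout.name!r}")
                if b.parameter not in BINDABLE_PARAMETERS:
                    raise ConfigError(
                        f"bank {bank_name!r}: unknown parameter {b.parameter!r}; "
                        f"bindable: {', '.join(BINDABLE_PARAMETERS)}")
                if b.element_id in seen:
                    raise ConfigError(
                        f"bank {bank_name!r}: element {b.element_id} bound twice")
                seen.add(b.element_id)
                for mid in b.meta_ids:
                    if mid not in self.layout:
                        raise ConfigError(
                            f"bank {bank_name!r}: meta element {mid} not in layout")
        for btn, bank in self.bank_buttons.items():
            if btn not in self.layout:
                raise ConfigError(f"bank button {btn} not in layout")
            if bank not in ("", "default") and bank not in self.banks:
                raise ConfigError(f"bank button {btn} targets unknown bank {bank!r}")


@dataclass
class TrajectoryRecord:
    """One applied controller event: which element moved, to what raw value,
    and the parameter value that resulted."""

    sim_index: int
    element_id: int
    raw_value: int
    parameter: str
    mapped_value: float
    units: str = ""
    timestamp: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrajectoryRecord":
        return cls(**d)


@dataclass
class SessionLog:
    """Replayable account of one session."""

    initial_parameters: dict
    initial_protocol: dict
    records: list = field(default_factory=list)
    final_parameters: dict = field(default_factory=dict)
    final_protocol: dict = field(default_factory=dict)
    version: int = LOG_FORMAT_VERSION

    def to_json(self) -> str:
        return json.dumps({
            "version": self.version,
            "initial_parameters": self.initial_parameters,
            "initial_protocol": self.initial_protocol,
            "records": [r.to_dict() for r in self.records],
            "final_parameters": self.final_parameters,
            "final_protocol": self.final_protocol,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SessionLog":
        d = json.loads(text)
        return cls(
            initial_parameters=d["initial_parameters"],
            initial_protocol=d["initial_protocol"],
            records=[TrajectoryRecord.from_dict(r) for r in d["records"]],
            final_parameters=d["final_parameters"],
            final_protocol=d["final_protocol"],
            version=d.get("version", LOG_FORMAT_VERSION),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "SessionLog":
        with open(path) as fh:
            return cls.from_json(fh.read())


@dataclass
class SessionResult:
    log: SessionLog
    final_trace: SimulationTrace
    n_simulations: int  # reruns after the baseline
    skipped_events: int = 0


class _Engine:
    """Shared event-application state machine.

    Both the live loop and :func:`replay` apply events through this one code
    path, so a replayed record goes through bit-identical arithmetic.
    Meta adjustments are always computed from the binding's *base* interval,
    so a meta knob's position, not its history, determines the live bounds.
    """

    def __init__(self, config: SessionConfig):
        self.config = config
        self.params = config.parameters
        self.protocol = config.protocol
        self.active_bank = "default"
        self._tables = {"default": config.bindings, **config.banks}
        # live interval + last primary raw per (bank, element)
        self._state = {}
        for bank, bindings in self._tables.items():
            for b in bindings:
                raw0 = ctl.unmap(self._current_value(b.parameter), b)
                self._state[(bank, b.element_id)] = {
                    "low": b.low, "high": b.high, "last_raw": raw0,
                }

    def _current_value(self, parameter: str) -> float:
        if parameter == "I_amp":
            return self.protocol.I_amp
        return getattr(self.params, parameter)

    def _set_value(self, parameter: str, value: float) -> None:
        if parameter == "I_amp":
            self.protocol = self.protocol.with_updates(I_amp=value)
        else:
            self.params = self.params.with_updates(**{parameter: value})

    def _bindings(self) -> list:
        return self._tables[self.active_bank]

    def apply_event(self, element_id: int, raw_value: int, sim_index: int):
        """Apply one event; returns a TrajectoryRecord if it changed the model,
        or None if it was a bank switch or an unbound element."""
        # bank switch buttons act on press only
        if element_id in self.config.bank_buttons:
            if raw_value == ctl.RAW_MAX:
                target = self.config.bank_buttons[element_id] or "default"
                if target == "default" or target in self._tables:
                    self.active_bank = "default" if target == "" else target
                    logger.info("bank switch -> %r", self.active_bank)
            return None

        bindings = self._bindings()
        primary = next((b for b in bindings if b.element_id == element_id), None)
        if primary is not None:
            st = self._state[(self.active_bank, element_id)]
            st["last_raw"] = raw_value
            value = ctl.map_raw(raw_value, primary, st["low"], st["high"])
            self._set_value(primary.parameter, value)
            return TrajectoryRecord(
                sim_index=sim_index, element_id=element_id, raw_value=raw_value,
                parameter=primary.parameter, mapped_value=value,
                units=PARAMETER_UNITS.get(primary.parameter, ""),
            )

        owner = next((b for b in bindings if element_id in b.meta_ids), None)
        if owner is not None:
            key = (self.active_bank, owner.element_id)
            st = self._state[key]
            try:
                new_low, new_high = ctl.apply_meta(
                    owner, raw_value, element_id, owner.low, owner.high)
                value = ctl.map_raw(st["last_raw"], owner, new_low, new_high)
            except ValueError as exc:
                logger.warning("meta event on element %d rejected: %s", element_id, exc)
                return None
            st["low"], st["high"] = new_low, new_high
            self._set_value(owner.parameter, value)
            return TrajectoryRecord(
                sim_index=sim_index, element_id=element_id, raw_value=raw_value,
                parameter=owner.parameter, mapped_value=value,
                units=PARAMETER_UNITS.get(owner.parameter, ""),
            )

        logger.warning("event on unbound element %d skipped", element_id)
        return None

    def snapshot(self) -> tuple:
        return self.params.to_dict(), self.protocol.to_dict()


def run_session(config: SessionConfig, max_sims: int | None = None,
                backend=None) -> SessionResult:
    """Run the closed loop until the backend is exhausted or ``max_sims``
    model reruns (beyond the baseline) have happened.

    One simulation per applied event by default; with ``config.coalesce``
    only the latest value per element in each poll batch is applied, for
    models too slow to keep up with a fast hand.
    """
    if backend is None:
        backend = ctl.open_backend(config.backend_spec)
    engine = _Engine(config)
    init_params, init_proto = engine.snapshot()
    log = SessionLog(initial_parameters=init_params, initial_protocol=init_proto)

    trace = simulate(engine.params, engine.protocol)  # baseline, sim_index 0
    sim_index = 0
    skipped = 0
    while not backend.exhausted:
        if max_sims is not None and sim_index >= max_sims:
            break
        events = ctl.poll(backend, coalesce=config.coalesce)
        if not events:
            if getattr(backend, "exhausted", False):
                break
            time.sleep(0.005)  # live backend idle; avoid a hot spin
            continue
        for ev in events:
            if max_sims is not None and sim_index >= max_sims:
                break
            record = engine.apply_event(ev.element_id, ev.raw_value, sim_index + 1)
            if record is None:
                skipped += 1
                continue
            sim_index += 1
            record.timestamp = time.time()
            trace = simulate(engine.params, engine.protocol)
            log.records.append(record)

    log.final_parameters, log.final_protocol = engine.snapshot()
    return SessionResult(log=log, final_trace=trace,
                         n_simulations=sim_index, skipped_events=skipped)


class ReplayError(ValueError):
    """Log and config are incompatible."""


def replay(log: SessionLog, config: SessionConfig) -> SimulationTrace:
    """Reapply a recorded session from its initial snapshot.

    Validates the log against the config up front (every recorded element
    must still be bound, every parameter known), then drives the same
    engine the live loop used.  The returned final trace is bit-identical
    to the live session's.
    """
    if log.version != LOG_FORMAT_VERSION:
        raise ReplayError(f"unsupported log version {log.version}")
    known = set()
    for bindings in [config.bindings, *config.banks.values()]:
        for b in bindings:
            known.add(b.element_id)
            known.update(b.meta_ids)
    known.update(config.bank_buttons)
    for r in log.records:
        if r.parameter not in BINDABLE_PARAMETERS:
            raise ReplayError(f"record references unknown parameter {r.parameter!r}")
        if r.element_id not in known:
            raise ReplayError(f"record references unbound element {r.element_id}")

    base_config = SessionConfig(
        layout=config.layout,
        bindings=config.bindings,
        parameters=HHParameters.from_dict(log.initial_parameters),
        protocol=StimulusProtocol.from_dict(log.initial_protocol),
        backend_spec=config.backend_spec,
        banks=config.banks,
        bank_buttons=config.bank_buttons,
    )
    engine = _Engine(base_config)
    for i, r in enumerate(log.records, start=1):
        engine.apply_event(r.element_id, r.raw_value, i)
    final_params, final_proto = engine.snapshot()
    if log.final_parameters and final_params != log.final_parameters:
        raise ReplayError("replayed parameters do not match the log's final snapshot")
    if log.final_protocol and final_proto != log.final_protocol:
        raise ReplayError("replayed protocol does not match the log's final snapshot")
    return simulate(engine.params, engine.protocol)


def write_trajectory_csv(log: SessionLog, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sim_index", "element_id", "parameter", "raw_value", "mapped_value"])
        for r in log.records:
            writer.writerow([r.sim_index, r.element_id, r.parameter,
                             r.raw_value, repr(r.mapped_value)])


def read_trajectory_csv(path) -> list:
    """Read back what :func:`write_trajectory_csv` wrote (round-trip exact)."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            rows.append(TrajectoryRecord(
                sim_index=int(row["sim_index"]),
                element_id=int(row["element_id"]),
                parameter=row["parameter"],
                raw_value=int(row["raw_value"]),
                mapped_value=float(row["mapped_value"]),
            ))
    return rows


def plot_trajectories(log: SessionLog, png_path=None, csv_path=None):
    """Parameter-trajectory plot: raw control value (0-127) vs simulation index.

    One line per touched parameter, mirroring how a tuning journey is
    usually inspected after the fact.  Returns the matplotlib figure; an
    empty log yields an empty (but valid) figure and a warning.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    if not log.records:
        logger.warning("plot_trajectories: empty session log, nothing to plot")
    by_param = {}
    for r in log.records:
        by_param.setdefault(r.parameter, ([], []))
        by_param[r.parameter][0].append(r.sim_index)
        by_param[r.parameter][1].append(r.raw_value)
    for name, (x, y) in by_param.items():
        ax.plot(x, y, marker="o", markersize=3, label=name)
    ax.set_xlabel("simulation index")
    ax.set_ylabel("control value")
    ax.set_ylim(0, 127)
    if by_param:
        ax.legend(fontsize=8)
    fig.tight_layout()
    if png_path is not None:
        fig.savefig(png_path, dpi=110)
    if csv_path is not None:
        write_trajectory_csv(log, csv_path)
    return fig
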