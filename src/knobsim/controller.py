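"""Control-surface event layer: device layouts, 7-bit events, backends, mappings.

A control surface (hardware or virtual) is reduced to a single contract: a
backend that, when polled, hands over ``(element ID, raw value)`` tuples for
every knob, slider or button the user touched since the last poll.  Raw
values are 7-bit (0-127), the data-byte range of MIDI control-change
messages.  Everything downstream — mapping raw positions into parameter
units, meta-elements that reshape a mapping's range on the fly — is pure
arithmetic on those tuples and is backend-agnostic.

The bundled default layout emulates the Evolution UC-33 class of devices:
33 continuous elements (knobs and sliders) plus 14 buttons.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "RAW_MAX",
    "ControlElement",
    "DeviceLayout",
    "ControlEvent",
    "ParameterBinding",
    "BackendError",
    "BackendClosedError",
    "VirtualBackend",
    "MidiBackend",
    "uc33_layout",
    "open_backend",
    "poll",
    "map_raw",
    "unmap",
    "apply_meta",
    "load_script",
    "save_script",
]

logger = logging.getLogger(__name__)

RAW_MAX = 127  # 7-bit MIDI data byte
_ELEMENT_KINDS = ("knob", "slider", "button")


@dataclass(frozen=True)
class ControlElement:
    element_id: int
    kind: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _ELEMENT_KINDS:
            raise ValueError(f"kind must be one of {_ELEMENT_KINDS}, got {self.kind!r}")


@dataclass
class DeviceLayout:
    name: str
    elements: list

    def __post_init__(self) -> None:
        ids = [e.element_id for e in self.elements]
        if len(ids) != len(set(ids)):
            raise ValueError("element_id values must be unique within a layout")
        self._by_id = {e.element_id: e for e in self.elements}

    def __contains__(self, element_id: int) -> bool:
        return element_id in self._by_id

    def get(self, element_id: int) -> ControlElement:
        return self._by_id[element_id]

    @property
    def continuous_count(self) -> int:
        return sum(1 for e in self.elements if e.kind in ("knob", "slider"))

    @property
    def button_count(self) -> int:
        return sum(1 for e in self.elements if e.kind == "button")


def uc33_layout() -> DeviceLayout:
    """Emulated UC-33-class layout: 24 knobs + 9 sliders, 14 buttons.

    Element IDs are assigned contiguously: 0-23 knobs, 24-32 sliders,
    33-46 buttons.
    """
    elements = [ControlElement(i, "knob", f"knob{i + 1}") for i in range(24)]
    elements += [ControlElement(24 + i, "slider", f"slider{i + 1}") for i in range(9)]
    elements += [ControlElement(33 + i, "button", f"button{i + 1}") for i in range(14)]
    return DeviceLayout(name="UC-33 emulation", elements=elements)


@dataclass(frozen=True)
class ControlEvent:
    element_id: int
    raw_value: int
    seq: int

    def __post_init__(self) -> None:
        if not 0 <= self.raw_value <= RAW_MAX:
            raise ValueError(f"raw_value must lie in [0, {RAW_MAX}], got {self.raw_value}")


@dataclass
class ParameterBinding:
    """Maps one continuous element onto one model parameter.

    ``map_kind`` is ``linear`` (raw 0..127 spans [low, high] affinely) or
    ``exponential`` (spans [low, high] geometrically; requires low > 0).
    ``meta_low_id``/``meta_high_id`` name optional elements that reshape the
    interval live; when both name the same element it widens or shortens the
    interval symmetrically about its center.
    """

    element_id: int
    parameter: str
    low: float
    high: float
    map_kind: str = "linear"
    meta_low_id: int | None = None
    meta_high_id: int | None = None

    def __post_init__(self) -> None:
        if self.map_kind not in ("linear", "exponential"):
            raise ValueError(f"map_kind must be 'linear' or 'exponential', got {self.map_kind!r}")
        _check_interval(self.low, self.high, self.map_kind)

    @property
    def meta_ids(self) -> set:
        return {i for i in (self.meta_low_id, self.meta_high_id) if i is not None}


def _check_interval(low: float, high: float, map_kind: str) -> None:
    if not (math.isfinite(low) and math.isfinite(high)):
        raise ValueError(f"bounds must be finite, got [{low}, {high}]")
    if not low < high:
        raise ValueError(f"need low < high, got [{low}, {high}]")
    if map_kind == "exponential" and low <= 0:
        raise ValueError(f"exponential mapping requires low > 0, got low={low}")


def map_raw(raw_value: int, binding: ParameterBinding,
            low: float | None = None, high: float | None = None) -> float:
    """Map a 7-bit raw value into parameter units.

    ``low``/``high`` override the binding's stored interval (they are the
    live, possibly meta-adjusted bounds).  Endpoints are exact: raw 0 maps
    to ``low`` and raw 127 to ``high`` in both map kinds.
    """
    if not 0 <= raw_value <= RAW_MAX:
        raise ValueError(f"raw_value must lie in [0, {RAW_MAX}], got {raw_value}")
    lo = binding.low if low is None else low
    hi = binding.high if high is None else high
    _check_interval(lo, hi, binding.map_kind)
    if raw_value == 0:
        return lo
    if raw_value == RAW_MAX:
        return hi
    frac = raw_value / RAW_MAX
    if binding.map_kind == "linear":
        return lo + frac * (hi - lo)
    return lo * (hi / lo) ** frac


def unmap(value: float, binding: ParameterBinding,
          low: float | None = None, high: float | None = None) -> int:
    """Nearest raw value whose mapping reproduces ``value``.

    Inverse of :func:`map_raw` rounded to the nearest integer position;
    values outside [low, high] are clamped to the endpoint and a warning is
    logged.  Round-trips exactly: unmap(map_raw(r)) == r for all r.
    """
    lo = binding.low if low is None else low
    hi = binding.high if high is None else high
    _check_interval(lo, hi, binding.map_kind)
    if value <= lo or value >= hi:
        if value < lo or value > hi:
            logger.warning(
                "unmap: value %g outside [%g, %g] for %s; clamping",
                value, lo, hi, binding.parameter,
            )
        return 0 if value <= lo else RAW_MAX
    if binding.map_kind == "linear":
        frac = (value - lo) / (hi - lo)
    else:
        frac = math.log(value / lo) / math.log(hi / lo)
    raw = round(frac * RAW_MAX)
    return min(RAW_MAX, max(0, raw))


def _meta_factor(meta_raw: int) -> float:
    """Exponential scale factor, x1/4 .. x4 with an exact neutral detent.

    raw 64 is the detent (factor 1); 0 maps exactly to 1/4 and 127 exactly
    to 4, with the two half-ranges scaled independently so all three anchor
    positions are exact.
    """
    if not 0 <= meta_raw <= RAW_MAX:
        raise ValueError(f"meta_raw must lie in [0, {RAW_MAX}], got {meta_raw}")
    if meta_raw >= 64:
        return 4.0 ** ((meta_raw - 64) / 63.0)
    return 4.0 ** ((meta_raw - 64) / 64.0)


def apply_meta(binding: ParameterBinding, meta_raw: int, meta_id: int,
               low: float, high: float) -> tuple:
    """Reshape a binding's live interval from a meta-element position.

    When ``meta_id`` serves as both the low and high meta element the
    interval's width is rescaled about its center by the exponential factor
    (detent at raw 64 leaves it unchanged).  When it is only the low (high)
    meta, the low (high) bound moves toward/away from the opposite bound on
    the same exponential scale.  Returns the new ``(low, high)``.
    """
    if meta_id not in binding.meta_ids:
        raise ValueError(f"element {meta_id} is not a meta element of {binding.parameter}")
    f = _meta_factor(meta_raw)
    if binding.meta_low_id == meta_id and binding.meta_high_id == meta_id:
        center = 0.5 * (low + high)
        half = 0.5 * (high - low) * f
        return center - half, center + half
    if binding.meta_low_id == meta_id:
        return high - (high - low) * f, high
    return low, low + (high - low) * f


class BackendError(RuntimeError):
    """Backend cannot be opened or is misconfigured."""


class BackendClosedError(BackendError):
    """Poll attempted on a closed or disconnected backend."""


class VirtualBackend:
    """Deterministic scripted controller: replays a fixed event list.

    ``events_per_poll`` limits how many events one poll hands over
    (``None`` = all pending), which lets tests exercise multi-poll
    delivery.  The backend is *exhausted* once every scripted event has
    been delivered.
    """

    def __init__(self, events, events_per_poll: int | None = None):
        self._events = list(events)
        self._cursor = 0
        self._batch = events_per_poll
        self.closed = False

    @classmethod
    def from_script(cls, path, events_per_poll: int | None = None) -> "VirtualBackend":
        return cls(load_script(path), events_per_poll=events_per_poll)

    @property
    def exhausted(self) -> bool:
        return self._cursor >= len(self._events)

    def poll_raw(self) -> list:
        if self.closed:
            raise BackendClosedError("virtual backend is closed")
        end = len(self._events) if self._batch is None else min(
            len(self._events), self._cursor + self._batch)
        out = self._events[self._cursor:end]
        self._cursor = end
        return out

    def close(self) -> None:
        self.closed = True


class MidiBackend:
    """Live MIDI input: control-change messages become ControlEvents 1:1.

    Requires the optional ``mido`` dependency and real hardware; it is never
    exercised by the automated tests.
    """

    def __init__(self, port_name: str):
        try:
            import mido
        except ImportError as exc:
            raise BackendError(
                "live MIDI support requires the optional 'mido' and "
                "'python-rtmidi' packages (pip install knobsim[midi])"
            ) from exc
        try:
            self._port = mido.open_input(port_name)
        except (OSError, ValueError) as exc:
            raise BackendError(f"cannot open MIDI port {port_name!r}: {exc}") from exc
        self._seq = 0
        self.closed = False

    @property
    def exhausted(self) -> bool:
        return False  # a live device never runs out of events

    def poll_raw(self) -> list:
        if self.closed:
            raise BackendClosedError("MIDI backend is closed")
        out = []
        for msg in self._port.iter_pending():
            if msg.type == "control_change":
                self._seq += 1
                out.append(ControlEvent(element_id=msg.control,
                                        raw_value=msg.value, seq=self._seq))
        return out

    def close(self) -> None:
        self._port.close()
        self.closed = True


def open_backend(spec: str):
    """Open a backend from a descriptor string.

    ``"virtual:<script.csv>"`` replays a scripted session (empty path gives
    an event-less backend); ``"midi:<port-name>"`` attaches to live
    hardware.
    """
    kind, sep, rest = spec.partition(":")
    if not sep:
        raise BackendError(
            f"malformed backend spec {spec!r}; expected 'virtual:<script>' or 'midi:<port>'")
    if kind == "virtual":
        if not rest:
            return VirtualBackend([])
        path = Path(rest)
        if not path.exists():
            raise BackendError(f"virtual backend script not found: {path}")
        return VirtualBackend.from_script(path)
    if kind == "midi":
        return MidiBackend(rest)
    raise BackendError(
        f"unknown backend kind {kind!r}; valid kinds are 'virtual' and 'midi'")


def poll(backend, coalesce: bool = False) -> list:
    """Drain all events accumulated since the previous poll, in order.

    With ``coalesce=True`` only the latest value per element survives, kept
    at its original arrival position of that last occurrence.
    """
    events = backend.poll_raw()
    if not coalesce or len(events) <= 1:
        return list(events)
    last = {}
    for ev in events:
        last[ev.element_id] = ev
    kept = set(id(ev) for ev in last.values())
    return [ev for ev in events if id(ev) in kept]


def load_script(path) -> list:
    """Read a scripted event list: CSV lines ``seq,element_id,raw_value``.

    Rejects out-of-range raw values and non-increasing sequence numbers at
    load time so a bad script never reaches the session loop.
    """
    events = []
    prev_seq = None
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if row[0].strip() == "seq":  # optional header
                continue
            if len(row) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'seq,element_id,raw_value'")
            seq, element_id, raw_value = (int(x) for x in row)
            if not 0 <= raw_value <= RAW_MAX:
                raise ValueError(
                    f"{path}:{lineno}: raw_value {raw_value} outside [0, {RAW_MAX}]")
            if prev_seq is not None and seq <= prev_seq:
                raise ValueError(f"{path}:{lineno}: seq must be strictly increasing")
            prev_seq = seq
            events.append(ControlEvent(element_id=element_id, raw_value=raw_value, seq=seq))
    return events


def save_script(events, path) -> None:
    """Write events in the same CSV dialect :func:`load_script` reads."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["seq", "element_id", "raw_value"])
        for ev in events:
            writer.writerow([ev.seq, ev.element_id, ev.raw_value])
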