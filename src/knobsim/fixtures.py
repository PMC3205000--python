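"""Scripted-session fixtures: random event scripts and the bundled
hand-tuning journeys that end in each firing regime.

``make_fixture`` produces a deterministic pseudo-random event script over
the bound primary elements of a binding table — the workhorse for replay
regression tests.  The bundled ``fit_<regime>.csv`` scripts are frozen
recordings of a plausible tuning journey from the regular-spiking baseline
to each regime's parameter neighbourhood, meant to be replayed against
``fitting_config.yaml``.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .controller import RAW_MAX, ControlEvent, save_script
from .session import SessionConfig

__all__ = [
    "make_fixture",
    "fitting_config_path",
    "fitting_script_path",
]


def make_fixture(seed: int, n_events: int, bindings, path=None) -> list:
    """Deterministic random event script over a binding table's primary
    elements; raw values uniform on 0..127.

    Pure function of its arguments: the same seed and bindings give a
    byte-identical script file.  Returns the event list; writes it to
    ``path`` if given.
    """
    if n_events < 0:
        raise ValueError(f"n_events must be >= 0, got {n_events}")
    element_ids = sorted(b.element_id for b in bindings)
    if n_events > 0 and not element_ids:
        raise ValueError("cannot script events without any bound elements")
    rng = np.random.default_rng(seed)
    events = []
    for i in range(n_events):
        eid = int(element_ids[rng.integers(0, len(element_ids))])
        raw = int(rng.integers(0, RAW_MAX + 1))
        events.append(ControlEvent(element_id=eid, raw_value=raw, seq=i + 1))
    if path is not None:
        save_script(events, path)
    return events


def _data_path(name: str):
    return resources.files("knobsim").joinpath(f"data/{name}")


def fitting_config_path():
    """Session config the bundled fitting scripts were recorded against."""
    return _data_path("fitting_config.yaml")


def fitting_script_path(regime: str):
    """Bundled tuning-journey script ending in the given regime."""
    path = _data_path(f"fit_{regime}.csv")
    if not path.is_file():
        raise KeyError(f"no bundled fitting script for regime {regime!r}")
    return path
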