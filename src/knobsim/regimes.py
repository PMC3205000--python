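"""Qualitative firing-regime classification and the bundled regime presets.

Three parameter sets ship with the package, one per qualitative response to
the step-current protocol:

``regular_spiking``
    Tonic firing throughout the stimulus.
``subthreshold_oscillations``
    No spikes; sustained membrane-potential oscillations riding on the
    depolarisation, produced by a weak-sodium / slow-potassium resonance.
``transient_spiking``
    One or a few spikes right after stimulus onset, silenced by deep, slow
    sodium inactivation.

Each preset was found by scripted exploration of the model itself and then
frozen together with declarative criteria (``expected_features``) that the
simulated trace must satisfy.  The numeric thresholds of the classifier are
package conventions, declared per preset and overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .model import HHParameters, StimulusProtocol, SimulationTrace, simulate

__all__ = [
    "RegimeCriteria",
    "RegimePreset",
    "classify_regime",
    "get_preset",
    "PRESET_NAMES",
]

PRESET_NAMES = ("regular_spiking", "subthreshold_oscillations", "transient_spiking")


@dataclass(frozen=True)
class RegimeCriteria:
    """Thresholds for the qualitative classifier.

    ``min_regular_spikes``: spikes needed to call firing regular (the last
    of them must fall in the final third of the stimulus window).
    ``transient_window_ms``: spikes are "transient" if all fall within this
    long a window after stimulus onset.
    ``min_oscillation_peaks`` / ``min_oscillation_amp_mV``: how many local
    voltage maxima, how far above the post-transient mean, count as
    subthreshold oscillations.
    """

    min_regular_spikes: int = 5
    transient_window_ms: float = 50.0
    min_oscillation_peaks: int = 2
    min_oscillation_amp_mV: float = 1.0


def classify_regime(trace: SimulationTrace, proto: StimulusProtocol,
                    criteria: RegimeCriteria = RegimeCriteria()) -> str:
    """Label a step-protocol trace as one of the three regimes or "other".

    Precedence: sustained firing across the window is regular spiking;
    firing confined to the onset window is transient spiking; a silent
    trace with enough post-onset ringing is subthreshold oscillation.
    """
    spikes = trace.spike_times
    w0, w1 = proto.t_on, proto.t_off
    if spikes:
        last_third = w0 + (2.0 / 3.0) * (w1 - w0)
        if len(spikes) >= criteria.min_regular_spikes and spikes[-1] >= last_third:
            return "regular_spiking"
        if all(s <= w0 + criteria.transient_window_ms for s in spikes):
            return "transient_spiking"
        return "other"
    # silent trace: look for ringing above the settled depolarised level
    in_late = (trace.t >= 0.5 * (w0 + w1)) & (trace.t <= w1)
    if not np.any(in_late):
        return "other"
    baseline = float(trace.V[in_late].mean())
    V = trace.V
    is_peak = (V[1:-1] > V[:-2]) & (V[1:-1] >= V[2:])
    peak_idx = np.nonzero(is_peak)[0] + 1
    n_peaks = 0
    for i in peak_idx:
        if w0 <= trace.t[i] <= w1 and V[i] >= baseline + criteria.min_oscillation_amp_mV:
            n_peaks += 1
    if n_peaks >= criteria.min_oscillation_peaks:
        return "subthreshold_oscillations"
    return "other"


@dataclass
class RegimePreset:
    name: str
    parameters: HHParameters
    protocol: StimulusProtocol
    expected_features: dict = field(default_factory=dict)
    criteria: RegimeCriteria = field(default_factory=RegimeCriteria)

    def run(self) -> SimulationTrace:
        return simulate(self.parameters, self.protocol)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "parameters": self.parameters.to_dict(),
            "protocol": self.protocol.to_dict(),
            "expected_features": dict(self.expected_features),
            "criteria": asdict(self.criteria),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegimePreset":
        return cls(
            name=d["name"],
            parameters=HHParameters.from_dict(d["parameters"]),
            protocol=StimulusProtocol.from_dict(d["protocol"]),
            expected_features=dict(d.get("expected_features", {})),
            criteria=RegimeCriteria(**d.get("criteria", {})),
        )


def _load_preset_file(name: str) -> RegimePreset:
    from importlib import resources

    import yaml

    ref = resources.files("knobsim").joinpath(f"data/{name}.yaml")
    with ref.open() as fh:
        return RegimePreset.from_dict(yaml.safe_load(fh))


def get_preset(name: str) -> RegimePreset:
    """Load one of the bundled regime presets by name."""
    if name not in PRESET_NAMES:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")
    return _load_preset_file(name)
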