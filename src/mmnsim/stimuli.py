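"""Stimulus sequences and phase-locked input trains.

Tones come in four flavours: two frequency channels (``standard`` /
``deviant``) crossed with two durations (short 50 ms / long 100 ms).
All rhythmic protocols place trials on a fixed slot grid with
inter-onset interval ``1000 / rate`` ms; long tones *start 50 ms before*
the slot onset so that they end at the same time the co-scheduled short
tone would end.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core.params import ParameterError

__all__ = [
    "ToneEvent",
    "StimulusProtocol",
    "PhaseLockedInputSpec",
    "make_stimulus_sequence",
    "phase_locked_pulse_times",
    "PROTOCOL_KINDS",
    "SHORT_MS",
    "LONG_MS",
    "TONE_TYPES",
]

SHORT_MS = 50.0
LONG_MS = 100.0

#: the four tone types used by the roving and random-control sequences
TONE_TYPES: List[Tuple[str, float]] = [
    ("standard", SHORT_MS),
    ("deviant", SHORT_MS),
    ("standard", LONG_MS),
    ("deviant", LONG_MS),
]

PROTOCOL_KINDS = (
    "frequency_deviant",
    "omission",
    "duration_deviant",
    "inverse_duration_deviant",
    "roving",
    "double_deviant",
    "random_control",
)


@dataclass(frozen=True)
class ToneEvent:
    onset: float                 # ms; actual tone onset (slot - 50 for long tones)
    duration: float              # ms; 0 for omissions
    frequency_label: str         # 'standard' or 'deviant' tuning channel
    is_omission: bool
    is_deviant_trial: bool
    slot_onset: float            # ms; the expected (grid) onset of the trial

    def __post_init__(self) -> None:
        if self.frequency_label not in ("standard", "deviant"):
            raise ParameterError(f"bad frequency label {self.frequency_label!r}")


@dataclass
class StimulusProtocol:
    kind: str
    rate: float                              # Hz
    events: List[ToneEvent]
    expected_onsets: List[float]             # the slot grid, one per trial
    n_warmup_trials: int = 0                 # trials skipped by default in metrics
    t_end: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ParameterError(f"unknown protocol kind {self.kind!r}")
        if self.t_end == 0.0 and self.expected_onsets:
            self.t_end = self.expected_onsets[-1] + 1000.0 / self.rate

    @property
    def deviant_onsets(self) -> List[float]:
        return [e.slot_onset for e in self.events if e.is_deviant_trial]

    @property
    def standard_onsets(self) -> List[float]:
        return [e.slot_onset for e in self.events if not e.is_deviant_trial]

    # ------------------------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "kind": self.kind,
            "rate": self.rate,
            "n_warmup_trials": self.n_warmup_trials,
            "t_end": self.t_end,
            "expected_onsets": list(self.expected_onsets),
            "events": [asdict(e) for e in self.events],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "StimulusProtocol":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        events = [ToneEvent(**e) for e in payload["events"]]
        return cls(
            kind=payload["kind"],
            rate=payload["rate"],
            events=events,
            expected_onsets=payload["expected_onsets"],
            n_warmup_trials=payload["n_warmup_trials"],
            t_end=payload["t_end"],
        )


def _tone(slot: float, label: str, duration: float, deviant: bool) -> ToneEvent:
    onset = slot - (duration - SHORT_MS)  # long tones start 50 ms early
    return ToneEvent(
        onset=onset,
        duration=duration,
        frequency_label=label,
        is_omission=False,
        is_deviant_trial=deviant,
        slot_onset=slot,
    )


def _omission(slot: float) -> ToneEvent:
    return ToneEvent(
        onset=slot,
        duration=0.0,
        frequency_label="standard",
        is_omission=True,
        is_deviant_trial=True,
        slot_onset=slot,
    )


def _euler_circuit_k4() -> List[int]:
    """Deterministic Eulerian circuit over the complete digraph on 4 nodes:
    a node sequence of length 13 whose 12 steps cover every ordered pair
    exactly once."""
    remaining = {i: [j for j in range(4) if j != i] for i in range(4)}
    # Hierholzer with smallest-successor-first; start at node 0
    stack, circuit = [0], []
    while stack:
        v = stack[-1]
        if remaining[v]:
            stack.append(remaining[v].pop(0))
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    return circuit


def make_stimulus_sequence(
    kind: str,
    n_pre_standards: int = 4,
    rate: float = 2.0,
    seed: int = 0,
    n_warmup_standards: int = 4,
    lead_time: float = 1000.0,
    n_slots: Optional[int] = None,
) -> StimulusProtocol:
    """Build a deterministic stimulus protocol.

    The four oddball kinds (and ``double_deviant``) present
    ``n_warmup_standards`` adaptation standards (skipped by the metrics
    by default), then ``n_pre_standards`` scored standards, then a
    single deviant slot.  Repetitions of the deviant measurement come
    from re-running with different seeds rather than from repeating
    deviants within one run, which would adapt the deviant pathway
    itself.

    ``roving`` emits runs of five identical tones covering all 12
    transitions between the four tone types, plus one omission after the
    first run of each type.  ``random_control`` draws a tone type
    independently at each slot (``n_slots`` slots, seeded).
    """
    if kind not in PROTOCOL_KINDS:
        raise ParameterError(f"unknown protocol kind {kind!r}")
    if n_pre_standards < 1:
        raise ParameterError("n_pre_standards must be >= 1")
    T = 1000.0 / rate
    events: List[ToneEvent] = []

    if kind in ("frequency_deviant", "omission", "duration_deviant",
                "inverse_duration_deviant", "double_deviant"):
        if kind == "inverse_duration_deviant":
            std = ("standard", LONG_MS)
        else:
            std = ("standard", SHORT_MS)
        dev = {
            "frequency_deviant": ("deviant", SHORT_MS),
            "omission": None,
            "duration_deviant": ("standard", LONG_MS),
            "inverse_duration_deviant": ("standard", SHORT_MS),
            "double_deviant": ("deviant", LONG_MS),
        }[kind]
        slot = lead_time
        for _ in range(n_warmup_standards + n_pre_standards):
            events.append(_tone(slot, std[0], std[1], False))
            slot += T
        if dev is None:
            events.append(_omission(slot))
        else:
            events.append(_tone(slot, dev[0], dev[1], True))
        slot += T
        warmup = n_warmup_standards

    elif kind == "roving":
        nodes = _euler_circuit_k4()
        slot = lead_time
        seen = set()
        for bi, node in enumerate(nodes):
            label, dur = TONE_TYPES[node]
            for k in range(5):
                deviant = (k == 0 and bi > 0)
                events.append(_tone(slot, label, dur, deviant))
                slot += T
            if node not in seen:
                seen.add(node)
                events.append(_omission(slot))
                slot += T
        warmup = 5

    elif kind == "random_control":
        rng = np.random.default_rng(seed)
        m = n_slots if n_slots is not None else (n_pre_standards + 1) * n_cycles
        slot = lead_time
        prev = None
        for _ in range(m):
            node = int(rng.integers(0, 4))
            label, dur = TONE_TYPES[node]
            deviant = prev is not None and node != prev
            events.append(_tone(slot, label, dur, deviant))
            prev = node
            slot += T
        warmup = n_pre_standards + 1

    onsets = [e.slot_onset for e in events]
    return StimulusProtocol(
        kind=kind,
        rate=rate,
        events=events,
        expected_onsets=onsets,
        n_warmup_trials=warmup,
    )


@dataclass(frozen=True)
class PhaseLockedInputSpec:
    """Rhythmic square-pulse drive delivered at a fixed phase of the
    presentation rhythm, with an optional fixed per-neuron phase jitter."""

    rate: float = 2.0            # Hz
    phase_offset: float = 0.0    # ms relative to the slot grid (-50 for EP2)
    jitter_theta: float = 0.0    # ms; per-neuron offset ~ U[-theta, theta]
    pulse_width: float = 25.0    # ms
    amplitude: float = 0.25      # nA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_theta < 0:
            raise ParameterError("jitter_theta must be >= 0")
        if self.pulse_width <= 0:
            raise ParameterError("pulse_width must be positive")


def phase_locked_pulse_times(
    spec: PhaseLockedInputSpec,
    duration: float,
    n_neurons: int,
    t_first: float = 0.0,
) -> List[np.ndarray]:
    """Per-neuron pulse-onset schedules.

    Neuron ``i`` pulses at ``t0_i + k * 1000/rate`` where
    ``t0_i = t_first + phase_offset + u_i`` and ``u_i`` is drawn once
    from ``U[-theta, theta]``.  With ``theta == 0`` every neuron pulses
    exactly on the phase grid.
    """
    if duration <= 0:
        raise ParameterError("duration must be positive")
    rng = np.random.default_rng(spec.seed)
    offsets = rng.uniform(-spec.jitter_theta, spec.jitter_theta, size=n_neurons)
    if spec.jitter_theta == 0.0:
        offsets = np.zeros(n_neurons)
    T = 1000.0 / spec.rate
    out = []
    for i in range(n_neurons):
        t0 = t_first + spec.phase_offset + offsets[i]
        ks = np.arange(np.ceil(-t0 / T), np.floor((duration - t0) / T) + 1)
        out.append(t0 + ks * T)
    return out
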