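"""Parameter containers for neurons, synapses and projections.

Unit conventions used throughout the package:

* time         -- ms
* potential    -- mV
* capacitance  -- pF
* conductance  -- nS
* current      -- nA at the public API (converted to pA internally)

With these units the membrane time constant ``Cm / g_leak`` comes out
directly in ms, which keeps the integrator free of unit conversions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "NeuronParams",
    "SynapseKinetics",
    "DepressionParams",
    "ProjectionSpec",
    "RECEPTORS",
]

#: receptor name -> channel index used by the simulation engine
RECEPTORS = {"AMPA": 0, "NMDA": 1, "GABA": 2}


class ParameterError(ValueError):
    """Raised when a parameter container violates its invariants."""


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire membrane parameters."""

    cm: float = 100.0          # pF
    g_leak: float = 10.0       # nS
    e_leak: float = -70.0      # mV
    v_thresh: float = -50.0    # mV
    v_reset: float = -65.0     # mV
    t_ref: float = 3.0         # ms

    def __post_init__(self) -> None:
        if self.cm <= 0:
            raise ParameterError(f"cm must be positive, got {self.cm}")
        if self.g_leak <= 0:
            raise ParameterError(f"g_leak must be positive, got {self.g_leak}")
        if self.v_reset >= self.v_thresh:
            raise ParameterError(
                f"v_reset ({self.v_reset}) must lie below v_thresh ({self.v_thresh})"
            )
        if self.t_ref < 0:
            raise ParameterError(f"t_ref must be non-negative, got {self.t_ref}")

    @property
    def tau_m(self) -> float:
        """Membrane time constant in ms."""
        return self.cm / self.g_leak

    def with_cm(self, cm: float) -> "NeuronParams":
        return replace(self, cm=cm)


@dataclass(frozen=True)
class SynapseKinetics:
    """Single-exponential conductance channel attached to a projection."""

    receptor: str              # one of RECEPTORS
    g_max: float               # nS, per synapse
    tau_decay: float = None    # ms; defaults per receptor
    e_rev: float = None        # mV; defaults per receptor
    mg_block: bool = True      # only meaningful for NMDA

    _TAU_DEFAULTS = {"AMPA": 2.0, "NMDA": 100.0, "GABA": 10.0}
    _EREV_DEFAULTS = {"AMPA": 0.0, "NMDA": 0.0, "GABA": -80.0}

    def __post_init__(self) -> None:
        if self.receptor not in RECEPTORS:
            raise ParameterError(f"unknown receptor {self.receptor!r}")
        if self.g_max < 0:
            raise ParameterError(f"g_max must be >= 0, got {self.g_max}")
        if self.tau_decay is None:
            object.__setattr__(self, "tau_decay", self._TAU_DEFAULTS[self.receptor])
        if self.e_rev is None:
            object.__setattr__(self, "e_rev", self._EREV_DEFAULTS[self.receptor])
        if self.tau_decay <= 0:
            raise ParameterError(f"tau_decay must be positive, got {self.tau_decay}")


@dataclass(frozen=True)
class DepressionParams:
    """Release-fraction model of short-term synaptic depression.

    ``d`` tracks the fraction of releasable vesicles: each presynaptic
    spike removes ``pv * d`` and between spikes ``d`` relaxes back to 1
    with time constant ``tau_d``.
    """

    pv: float = 0.4            # release fraction per spike, in (0, 1]
    tau_d: float = 2000.0      # ms

    def __post_init__(self) -> None:
        if not (0.0 < self.pv <= 1.0):
            raise ParameterError(f"pv must lie in (0, 1], got {self.pv}")
        if self.tau_d <= 0:
            raise ParameterError(f"tau_d must be positive, got {self.tau_d}")


@dataclass(frozen=True)
class ProjectionSpec:
    """Bernoulli-wired projection between two populations."""

    source: str
    target: str
    p_connect: float
    kinetics: Sequence[SynapseKinetics]
    depression: Optional[DepressionParams] = None
    delay: float = 0.0         # ms; the engine enforces a one-step minimum
    seed: int = 0
    plastic: bool = False      # STDP-governed weights (see mmnsim.synfire)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_connect <= 1.0):
            raise ParameterError(f"p_connect must lie in [0, 1], got {self.p_connect}")
        if self.delay < 0:
            raise ParameterError(f"delay must be >= 0, got {self.delay}")
        if not self.kinetics:
            raise ParameterError("projection needs at least one kinetics entry")
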