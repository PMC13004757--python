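"""Spike records: the universal simulation output.

A :class:`SpikeRecord` stores every spike as ``(time_ms, population,
neuron_index)`` where ``neuron_index`` is local to its population.
Records persist as a delimited text file plus a small JSON sidecar
(`t_end`, seed, spec hash) so that the artifacts survive text-only
round trips.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = ["SpikeRecord"]


@dataclass
class SpikeRecord:
    times: np.ndarray                 # ms, sorted (globally nondecreasing)
    neurons: np.ndarray               # local neuron index within population
    pop_ids: np.ndarray               # index into `populations`
    populations: List[str]            # population names, order defines ids
    pop_sizes: List[int]
    t_end: float
    seed: Optional[int] = None
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.neurons = np.asarray(self.neurons, dtype=np.int64)
        self.pop_ids = np.asarray(self.pop_ids, dtype=np.int64)
        if not (len(self.times) == len(self.neurons) == len(self.pop_ids)):
            raise ValueError("times, neurons and pop_ids must have equal length")
        if self.times.size:
            if self.times.min() < 0 or self.times.max() > self.t_end + 1e-9:
                raise ValueError("spike times must lie in [0, t_end]")
        for pid, nid in zip(self.pop_ids, self.neurons):
            pass  # validated vectorized below
        if self.pop_ids.size:
            sizes = np.asarray(self.pop_sizes)
            if self.pop_ids.min() < 0 or self.pop_ids.max() >= len(self.populations):
                raise ValueError("invalid population id")
            if np.any(self.neurons < 0) or np.any(self.neurons >= sizes[self.pop_ids]):
                raise ValueError("neuron index out of range for its population")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n_spikes(self) -> int:
        return len(self)

    def population(self, name: str) -> Tuple[np.ndarray, np.ndarray]:
        """Return ``(times, neuron_indices)`` of one population's spikes."""
        pid = self.populations.index(name)
        sel = self.pop_ids == pid
        return self.times[sel], self.neurons[sel]

    def pop_spike_times(self, name: str) -> np.ndarray:
        """Pooled, sorted spike times of a population."""
        t, _ = self.population(name)
        return np.sort(t)

    # ------------------------------------------------------------------
    # persistence
    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Write ``<path>`` (TSV: time_ms, population, neuron_index) and
        ``<path>.json`` with the record metadata."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("time_ms\tpopulation\tneuron_index\n")
            for t, pid, nid in zip(self.times, self.pop_ids, self.neurons):
                fh.write(f"{t:.6f}\t{self.populations[pid]}\t{nid}\n")
        sidecar = {
            "t_end": self.t_end,
            "seed": self.seed,
            "populations": self.populations,
            "pop_sizes": self.pop_sizes,
            "meta": self.meta,
        }
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, path) -> "SpikeRecord":
        path = Path(path)
        with open(path.with_suffix(path.suffix + ".json")) as fh:
            sidecar = json.load(fh)
        populations = sidecar["populations"]
        lut = {name: i for i, name in enumerate(populations)}
        times, neurons, pop_ids = [], [], []
        with open(path) as fh:
            next(fh)  # header
            for line in fh:
                t, pop, nid = line.rstrip("\n").split("\t")
                times.append(float(t))
                pop_ids.append(lut[pop])
                neurons.append(int(nid))
        return cls(
            times=np.array(times, dtype=float),
            neurons=np.array(neurons, dtype=np.int64),
            pop_ids=np.array(pop_ids, dtype=np.int64),
            populations=populations,
            pop_sizes=sidecar["pop_sizes"],
            t_end=sidecar["t_end"],
            seed=sidecar["seed"],
            meta=sidecar.get("meta", {}),
        )
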