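"""Network assembly: populations, projections and input schedules.

A :class:`NetworkSpec` is a declarative description; :func:`compile_network`
resolves it into the flat arrays consumed by the integration kernel.
Adjacency is derived deterministically from each projection's seed, so a
spec (plus seeds) fully determines the simulated network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .connect import bernoulli_connect, sample_heterogeneous
from .params import (
    RECEPTORS,
    DepressionParams,
    NeuronParams,
    ParameterError,
    ProjectionSpec,
    SynapseKinetics,
)

__all__ = [
    "PopulationSpec",
    "NetworkSpec",
    "CurrentPulse",
    "CompiledNetwork",
    "compile_network",
]


@dataclass
class PopulationSpec:
    """A homogeneous (up to per-neuron Cm heterogeneity) neuron group."""

    name: str
    n: int
    neuron: NeuronParams = field(default_factory=NeuronParams)
    excitatory: bool = True
    noise_sd: float = 0.0              # nA; white current noise, see engine
    cm_values: Optional[np.ndarray] = None  # per-neuron Cm override (pF)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ParameterError(f"population {self.name}: n must be >= 1")
        if self.cm_values is not None:
            self.cm_values = np.asarray(self.cm_values, dtype=float)
            if self.cm_values.shape != (self.n,):
                raise ParameterError(
                    f"population {self.name}: cm_values must have shape ({self.n},)"
                )
            if np.any(self.cm_values <= 0):
                raise ParameterError(f"population {self.name}: cm_values must be > 0")

    def sample_cm(self, rel_sd: float, seed: int) -> "PopulationSpec":
        """Return a copy with per-neuron capacitances drawn around the mean."""
        cm = sample_heterogeneous(self.neuron.cm, rel_sd, self.n, seed)
        return replace(self, cm_values=cm)


@dataclass(frozen=True)
class CurrentPulse:
    """Square current pulse delivered to one neuron or a whole population."""

    population: str
    t_start: float                      # ms
    t_end: float                        # ms
    amplitude: float                    # nA
    neuron: Optional[int] = None        # None -> all neurons of population

    def __post_init__(self) -> None:
        if self.t_end < self.t_start:
            raise ParameterError("pulse t_end must be >= t_start")


@dataclass
class NetworkSpec:
    populations: List[PopulationSpec]
    projections: List[ProjectionSpec] = field(default_factory=list)
    nmda_mg_block: bool = True
    seed: int = 0
    efficacy_includes_pv: bool = False

    def __post_init__(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ParameterError("duplicate population names")
        lut = set(names)
        for proj in self.projections:
            if proj.source not in lut or proj.target not in lut:
                raise ParameterError(
                    f"projection {proj.source}->{proj.target} references "
                    "an unknown population"
                )

    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def names(self) -> List[str]:
        return [p.name for p in self.populations]

    @property
    def n_neurons(self) -> int:
        return sum(p.n for p in self.populations)

    def ablate(self, names: Sequence[str]) -> "NetworkSpec":
        """Return a copy without the listed populations and any projection
        touching them."""
        drop = set(names)
        unknown = drop - set(self.names)
        if unknown:
            raise ParameterError(f"cannot ablate unknown populations: {sorted(unknown)}")
        pops = [p for p in self.populations if p.name not in drop]
        projs = [
            pr for pr in self.projections if pr.source not in drop and pr.target not in drop
        ]
        return replace(self, populations=pops, projections=projs)


# ----------------------------------------------------------------------
# compilation to flat arrays
# ----------------------------------------------------------------------

@dataclass
class CompiledNetwork:
    """Flat, engine-ready representation of a :class:`NetworkSpec`."""

    spec: NetworkSpec
    n: int
    offsets: Dict[str, int]
    sizes: Dict[str, int]
    # per neuron
    cm: np.ndarray
    g_leak: np.ndarray
    e_leak: np.ndarray
    v_th: np.ndarray
    v_reset: np.ndarray
    t_ref: np.ndarray
    noise_sd: np.ndarray               # pA
    # per synapse (CSR sorted by presynaptic neuron)
    indptr: np.ndarray
    syn_pre: np.ndarray
    syn_post: np.ndarray
    syn_w: np.ndarray                  # nS
    syn_rec: np.ndarray                # channel index
    syn_delay_ms: np.ndarray
    syn_pv: np.ndarray                 # 0 -> no depression
    syn_taud: np.ndarray
    syn_stdp: np.ndarray               # bool
    syn_group: np.ndarray              # int32, -1 -> untracked
    rev_indptr: np.ndarray             # reverse CSR over plastic synapses
    rev_syn: np.ndarray
    tau_syn: np.ndarray
    e_syn: np.ndarray
    mg_on: bool

    def global_index(self, population: str, neuron: int = 0) -> int:
        return self.offsets[population] + neuron

    def pop_of(self, gidx: np.ndarray) -> np.ndarray:
        bounds = np.array([self.offsets[p.name] for p in self.spec.populations])
        return np.searchsorted(bounds, gidx, side="right") - 1


def compile_network(
    spec: NetworkSpec,
    syn_groups: Optional[Dict[str, int]] = None,
) -> CompiledNetwork:
    """Resolve a :class:`NetworkSpec` into flat arrays.

    ``syn_groups`` optionally maps ``"source->target"`` projection keys to
    a group id; synapses of those projections are tagged so the engine
    can record their mean weight over time (used for plastic feedback
    synapses).
    """
    offsets: Dict[str, int] = {}
    sizes: Dict[str, int] = {}
    off = 0
    for pop in spec.populations:
        offsets[pop.name] = off
        sizes[pop.name] = pop.n
        off += pop.n
    n = off

    cm = np.empty(n)
    g_leak = np.empty(n)
    e_leak = np.empty(n)
    v_th = np.empty(n)
    v_reset = np.empty(n)
    t_ref = np.empty(n)
    noise_sd = np.zeros(n)
    for pop in spec.populations:
        sl = slice(offsets[pop.name], offsets[pop.name] + pop.n)
        cm[sl] = pop.cm_values if pop.cm_values is not None else pop.neuron.cm
        g_leak[sl] = pop.neuron.g_leak
        e_leak[sl] = pop.neuron.e_leak
        v_th[sl] = pop.neuron.v_thresh
        v_reset[sl] = pop.neuron.v_reset
        t_ref[sl] = pop.neuron.t_ref
        noise_sd[sl] = pop.noise_sd * 1000.0  # nA -> pA

    pre_l: List[np.ndarray] = []
    post_l: List[np.ndarray] = []
    w_l: List[np.ndarray] = []
    rec_l: List[np.ndarray] = []
    delay_l: List[np.ndarray] = []
    pv_l: List[np.ndarray] = []
    taud_l: List[np.ndarray] = []
    stdp_l: List[np.ndarray] = []
    group_l: List[np.ndarray] = []

    mg_flags = set()
    for proj in spec.projections:
        edges = bernoulli_connect(
            sizes[proj.source], sizes[proj.target], proj.p_connect, proj.seed
        )
        if edges.size == 0:
            continue
        gpre = edges[:, 0].astype(np.int64) + offsets[proj.source]
        gpost = edges[:, 1].astype(np.int64) + offsets[proj.target]
        key = f"{proj.source}->{proj.target}"
        gid = -1 if syn_groups is None else syn_groups.get(key, -1)
        for kin in proj.kinetics:
            m = len(gpre)
            pre_l.append(gpre)
            post_l.append(gpost)
            w_l.append(np.full(m, kin.g_max))
            rec_l.append(np.full(m, RECEPTORS[kin.receptor], dtype=np.int8))
            delay_l.append(np.full(m, proj.delay))
            if proj.depression is not None:
                pv_l.append(np.full(m, proj.depression.pv))
                taud_l.append(np.full(m, proj.depression.tau_d))
            else:
                pv_l.append(np.zeros(m))
                taud_l.append(np.full(m, 1.0))
            stdp_l.append(np.full(m, proj.plastic, dtype=bool))
            group_l.append(np.full(m, gid, dtype=np.int32))
            if kin.receptor == "NMDA":
                mg_flags.add(bool(kin.mg_block))

    if len(mg_flags) > 1:
        raise ParameterError("mixed NMDA mg_block settings are not supported")
    mg_on = spec.nmda_mg_block and (True in mg_flags if mg_flags else True)

    if pre_l:
        syn_pre = np.concatenate(pre_l)
        order = np.argsort(syn_pre, kind="stable")
        syn_pre = syn_pre[order]
        syn_post = np.concatenate(post_l)[order]
        syn_w = np.concatenate(w_l)[order]
        syn_rec = np.concatenate(rec_l)[order]
        syn_delay = np.concatenate(delay_l)[order]
        syn_pv = np.concatenate(pv_l)[order]
        syn_taud = np.concatenate(taud_l)[order]
        syn_stdp = np.concatenate(stdp_l)[order]
        syn_group = np.concatenate(group_l)[order]
    else:
        syn_pre = np.empty(0, dtype=np.int64)
        syn_post = np.empty(0, dtype=np.int64)
        syn_w = np.empty(0)
        syn_rec = np.empty(0, dtype=np.int8)
        syn_delay = np.empty(0)
        syn_pv = np.empty(0)
        syn_taud = np.empty(0)
        syn_stdp = np.empty(0, dtype=bool)
        syn_group = np.empty(0, dtype=np.int32)

    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, syn_pre + 1, 1)
    indptr = np.cumsum(indptr)

    # reverse CSR over plastic synapses, indexed by postsynaptic neuron
    plastic_idx = np.flatnonzero(syn_stdp)
    rev_indptr = np.zeros(n + 1, dtype=np.int64)
    if plastic_idx.size:
        posts = syn_post[plastic_idx]
        order = np.argsort(posts, kind="stable")
        rev_syn = plastic_idx[order].astype(np.int64)
        np.add.at(rev_indptr, posts + 1, 1)
        rev_indptr = np.cumsum(rev_indptr)
    else:
        rev_syn = np.empty(0, dtype=np.int64)
        rev_indptr = np.cumsum(rev_indptr)

    tau_syn = np.array([2.0, 100.0, 10.0])
    e_syn = np.array([0.0, 0.0, -80.0])
    # honour per-projection kinetics overrides where supplied (single set)
    taus: Dict[int, float] = {}
    erevs: Dict[int, float] = {}
    for proj in spec.projections:
        for kin in proj.kinetics:
            ch = RECEPTORS[kin.receptor]
            if ch in taus and (taus[ch] != kin.tau_decay or erevs[ch] != kin.e_rev):
                raise ParameterError(
                    f"conflicting kinetics for receptor {kin.receptor}: the engine "
                    "supports one (tau_decay, e_rev) per receptor type"
                )
            taus[ch] = kin.tau_decay
            erevs[ch] = kin.e_rev
    for ch, tau in taus.items():
        tau_syn[ch] = tau
        e_syn[ch] = erevs[ch]

    return CompiledNetwork(
        spec=spec,
        n=n,
        offsets=offsets,
        sizes=sizes,
        cm=cm,
        g_leak=g_leak,
        e_leak=e_leak,
        v_th=v_th,
        v_reset=v_reset,
        t_ref=t_ref,
        noise_sd=noise_sd,
        indptr=indptr,
        syn_pre=syn_pre,
        syn_post=syn_post,
        syn_w=syn_w,
        syn_rec=syn_rec,
        syn_delay_ms=syn_delay,
        syn_pv=syn_pv,
        syn_taud=syn_taud,
        syn_stdp=syn_stdp,
        syn_group=syn_group,
        rev_indptr=rev_indptr,
        rev_syn=rev_syn,
        tau_syn=tau_syn,
        e_syn=e_syn,
        mg_on=mg_on,
    )
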