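"""Synfire chain with plastic feedback synapses.

A base population drives a feedforward chain of excitatory populations
(static AMPA synapses, 5-ms delays, Bernoulli p = 0.5); every chain
population feeds back onto the base population through synapses whose
weights follow a pair-based STDP rule with exponentially decaying
traces:

    on a presynaptic spike:   w <- clip(w + A_post);  A_pre  += A_plus
    on a postsynaptic spike:  w <- clip(w + A_pre);   A_post += A_minus

with both traces decaying with time constant ``tau_a`` between events
and weights clipped to [w_min, w_max].  Simultaneous pre/post events
resolve pre-before-post.  Each excitatory population is paired with an
inhibitory partner population that truncates its bursts.

Rhythmic square-pulse stimulation of the base population entrains the
loop: populations that fire shortly before the next base activation are
potentiated until the network reverberates as a synfire ring after the
stimulus ceases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    CurrentPulse,
    NeuronParams,
    NetworkSpec,
    PopulationSpec,
    ProjectionSpec,
    SimulationResult,
    SynapseKinetics,
    integrate_network,
)
from .core.params import ParameterError
from .metrics import detect_bursts, score_entrainment

__all__ = [
    "StdpParams",
    "StdpSynapseState",
    "stdp_update",
    "SynfireConfig",
    "build_synfire_network",
    "run_entrainment",
    "entrainment_grid",
    "propagation_time",
]


# ----------------------------------------------------------------------
# event-level STDP (the reference implementation; the engine applies the
# same rule inline)
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class StdpParams:
    a_plus: float = 0.029            # nS, presynaptic trace increment
    alpha: float = -1.2              # A_minus = alpha * A_plus
    tau_a: float = 20.0              # ms
    w_min: float = 0.0               # nS
    w_max: float = 2.4               # nS (2400 pS)
    w_init: Optional[float] = None   # defaults to a_plus

    def __post_init__(self) -> None:
        if self.a_plus <= 0:
            raise ParameterError("a_plus must be positive")
        if self.alpha >= 0:
            raise ParameterError("alpha must be negative (A_minus < 0)")
        if self.tau_a <= 0:
            raise ParameterError("tau_a must be positive")
        if self.w_init is None:
            object.__setattr__(self, "w_init", self.a_plus)
        if not (self.w_min <= self.w_init <= self.w_max):
            raise ParameterError("w_init must lie within [w_min, w_max]")

    @property
    def a_minus(self) -> float:
        return self.alpha * self.a_plus


@dataclass
class StdpSynapseState:
    w: float
    a_pre: float = 0.0     # >= 0
    a_post: float = 0.0    # <= 0
    t_last: float = -np.inf


def stdp_update(
    state: StdpSynapseState, event: str, t: float, params: StdpParams
) -> StdpSynapseState:
    """Apply one pre- or postsynaptic spike event at time ``t``.

    Traces decay from the state's last-update time; on ``"pre"`` the
    weight absorbs the (negative) postsynaptic trace before the
    presynaptic trace is incremented, and vice versa on ``"post"``.
    """
    if event not in ("pre", "post"):
        raise ParameterError("event must be 'pre' or 'post'")
    if t < state.t_last:
        raise ParameterError("events must be processed in time order")
    decay = np.exp(-(t - state.t_last) / params.tau_a) if np.isfinite(state.t_last) else 0.0
    a_pre = state.a_pre * decay
    a_post = state.a_post * decay
    w = state.w
    if event == "pre":
        w = float(np.clip(w + a_post, params.w_min, params.w_max))
        a_pre += params.a_plus
    else:
        w = float(np.clip(w + a_pre, params.w_min, params.w_max))
        a_post += params.a_minus
    return StdpSynapseState(w=w, a_pre=a_pre, a_post=a_post, t_last=t)


# ----------------------------------------------------------------------
# network construction
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SynfireConfig:
    n_chain_pops: int = 70
    n_per_pop: int = 50
    p_connect: float = 0.5
    ff_delay: float = 5.0            # ms, feedforward transmission delay
    fb_delay: float = 5.0            # ms, plastic feedback delay
    stim_rate: float = 2.0           # Hz
    stim_duration: float = 12000.0   # ms
    post_duration: float = 2500.0    # ms simulated after cessation
    stim_amplitude: float = 3.0      # nA square pulse to the base population
    stim_width: float = 22.0         # ms
    cm: float = 300.0                # pF chain membrane capacitance
    base_cm: float = 500.0           # pF base population (less excitable: only
                                     # the stimulus or strong volleys fire it)
    tau_ampa: float = 4.0            # ms AMPA decay within this network
    tau_gaba: float = 30.0           # ms GABA decay (long, suppresses doublets)
    w_ff: float = 2.3                # nS, static feedforward weight (calibrated)
    w_ei: float = 1.2                # nS, excitatory -> inhibitory partner
    w_ie: float = 6.0                # nS, inhibitory partner -> excitatory
    base_w_ei: float = 2.0           # nS, base -> its partner
    base_w_ie: float = 6.0           # nS, partner -> base (burst truncation)
    inh_delay: float = 2.0           # ms
    noise_sd: float = 0.1            # nA, base population only
    rel_sd: float = 0.1              # Cm heterogeneity
    inhibitory_partners: bool = True

    def __post_init__(self) -> None:
        if self.n_chain_pops < 1 or self.n_per_pop < 1:
            raise ParameterError("population counts must be >= 1")
        if self.ff_delay < 0:
            raise ParameterError("delay must be >= 0")


def chain_pop_name(i: int) -> str:
    return f"C{i:03d}"


def build_synfire_network(
    cfg: SynfireConfig, seed: int = 0, stdp: Optional[StdpParams] = None
) -> NetworkSpec:
    """Base population + feedforward chain + inhibitory partners + plastic
    feedback synapses (initialized at ``w_init``) from every chain
    population back to the base population."""
    neuron = NeuronParams(cm=cfg.cm)
    base_neuron = NeuronParams(cm=cfg.base_cm)
    rng = np.random.default_rng(seed)
    w_init = stdp.w_init if stdp is not None else StdpParams().w_init

    pops: List[PopulationSpec] = []
    projections: List[ProjectionSpec] = []

    base = PopulationSpec("base", cfg.n_per_pop, neuron=base_neuron,
                          noise_sd=cfg.noise_sd)
    pops.append(base.sample_cm(cfg.rel_sd, int(rng.integers(0, 2**31))))
    exc_names = ["base"]
    for i in range(cfg.n_chain_pops):
        name = chain_pop_name(i + 1)
        pop = PopulationSpec(name, cfg.n_per_pop, neuron=neuron)
        pops.append(pop.sample_cm(cfg.rel_sd, int(rng.integers(0, 2**31))))
        exc_names.append(name)

    def rseed() -> int:
        return int(rng.integers(0, 2**31))

    # feedforward chain: base -> C1 -> C2 -> ... -> C_n
    for pre, post in zip(exc_names[:-1], exc_names[1:]):
        projections.append(
            ProjectionSpec(pre, post, cfg.p_connect,
                           [SynapseKinetics("AMPA", cfg.w_ff, tau_decay=cfg.tau_ampa)],
                           delay=cfg.ff_delay, seed=rseed())
        )

    # inhibitory partners, bidirectional
    if cfg.inhibitory_partners:
        for name in exc_names:
            iname = "I" + name
            ipop = PopulationSpec(iname, cfg.n_per_pop, neuron=neuron,
                                  excitatory=False)
            pops.append(ipop.sample_cm(cfg.rel_sd, rseed()))
            w_ei = cfg.base_w_ei if name == "base" else cfg.w_ei
            w_ie = cfg.base_w_ie if name == "base" else cfg.w_ie
            projections.append(
                ProjectionSpec(name, iname, cfg.p_connect,
                               [SynapseKinetics("AMPA", w_ei, tau_decay=cfg.tau_ampa)],
                               delay=cfg.inh_delay, seed=rseed())
            )
            projections.append(
                ProjectionSpec(iname, name, cfg.p_connect,
                               [SynapseKinetics("GABA", w_ie, tau_decay=cfg.tau_gaba)],
                               delay=cfg.inh_delay, seed=rseed())
            )

    # plastic feedback synapses onto the base population
    for i in range(cfg.n_chain_pops):
        projections.append(
            ProjectionSpec(chain_pop_name(i + 1), "base", cfg.p_connect,
                           [SynapseKinetics("AMPA", w_init, tau_decay=cfg.tau_ampa)],
                           delay=cfg.fb_delay, seed=rseed(), plastic=True)
        )

    return NetworkSpec(populations=pops, projections=projections, seed=seed)


def _stim_pulses(cfg: SynfireConfig, rng: Optional[np.random.Generator] = None,
                 poisson: bool = False) -> List[CurrentPulse]:
    T = 1000.0 / cfg.stim_rate
    pulses = []
    if poisson:
        if rng is None:
            raise ParameterError("poisson stimulation needs an RNG")
        t = 0.0
        while True:
            t += rng.exponential(T)
            if t >= cfg.stim_duration:
                break
            pulses.append(CurrentPulse("base", t, t + cfg.stim_width,
                                       cfg.stim_amplitude))
    else:
        t = 0.0
        while t < cfg.stim_duration:
            pulses.append(CurrentPulse("base", t, t + cfg.stim_width,
                                       cfg.stim_amplitude))
            t += T
    return pulses


def propagation_time(
    cfg: SynfireConfig, seed: int = 0, dt: float = 0.1
) -> Tuple[float, SimulationResult]:
    """Time from a single stimulus onset to the last spike of the final
    chain population's activation burst (STDP disabled)."""
    net = build_synfire_network(cfg, seed=seed)
    pulses = [CurrentPulse("base", 0.0, cfg.stim_width, cfg.stim_amplitude)]
    # generous horizon: expected sweep plus margin
    horizon = cfg.n_chain_pops * (cfg.ff_delay + 5.0) + 300.0
    res = integrate_network(net, pulses, horizon, dt=dt, seed=seed)
    last_name = chain_pop_name(cfg.n_chain_pops)
    t_last_pop = res.record.pop_spike_times(last_name)
    if t_last_pop.size == 0:
        return np.nan, res
    bursts = detect_bursts(t_last_pop, max_isi=50.0)
    return float(bursts[0].end), res


def run_entrainment(
    cfg: SynfireConfig,
    stdp: StdpParams,
    seed: int = 0,
    dt: float = 0.1,
    poisson: bool = False,
    snapshot_interval: float = 250.0,
    runaway_rate: float = 200.0,
) -> Dict:
    """Entrain the chain to rhythmic (or Poisson-timed control)
    stimulation and score post-cessation activity.

    Returns a dict with the simulation result, relative and absolute
    entrainment scores, per-population mean feedback-weight
    trajectories, and a runaway-activity flag (base-population firing
    rate above ``runaway_rate`` spikes/s/neuron in any 500-ms bin).
    """
    rng = np.random.default_rng(seed)
    net = build_synfire_network(cfg, seed=seed, stdp=stdp)
    pulses = _stim_pulses(cfg, rng=rng, poisson=poisson)
    duration = cfg.stim_duration + cfg.post_duration
    groups = {f"{chain_pop_name(i + 1)}->base": i for i in range(cfg.n_chain_pops)}
    res = integrate_network(
        net,
        pulses,
        duration,
        dt=dt,
        seed=int(rng.integers(0, 2**31)),
        stdp={
            "a_plus": stdp.a_plus,
            "a_minus": stdp.a_minus,
            "tau_a": stdp.tau_a,
            "w_min": stdp.w_min,
            "w_max": stdp.w_max,
        },
        syn_groups=groups,
        snapshot_interval=snapshot_interval,
        max_spikes=30_000_000,
    )
    base_times = res.record.pop_spike_times("base")
    rel = score_entrainment(base_times, cfg.stim_duration, rate=cfg.stim_rate,
                            mode="relative")
    absolute = score_entrainment(base_times, cfg.stim_duration,
                                 rate=cfg.stim_rate, mode="absolute")
    # runaway diagnostic
    bins = np.arange(0.0, duration + 500.0, 500.0)
    hist, _ = np.histogram(base_times, bins=bins)
    rate_per_neuron = hist / cfg.n_per_pop / 0.5
    runaway = bool(np.any(rate_per_neuron > runaway_rate)) or res.overflow
    return {
        "result": res,
        "relative": rel,
        "absolute": absolute,
        "runaway": runaway,
        "weight_times": res.weight_times,
        "weights": res.weight_snapshots,
    }


def entrainment_grid(
    a_plus_values: Sequence[float],
    alpha_values: Sequence[float],
    cfg: Optional[SynfireConfig] = None,
    reps: int = 20,
    seed: int = 0,
    dt: float = 0.1,
) -> Dict:
    """Fraction of repetitions with expected-time and with
    unexpected-time post-cessation activity, per (A_plus, alpha) cell
    (absolute scorer)."""
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    if cfg is None:
        cfg = SynfireConfig()
    rng = np.random.default_rng(seed)
    seeds = [int(rng.integers(0, 2**31)) for _ in range(reps)]
    expected = np.zeros((len(alpha_values), len(a_plus_values)))
    unexpected = np.zeros_like(expected)
    for ia, alpha in enumerate(alpha_values):
        for ip, a_plus in enumerate(a_plus_values):
            stdp = StdpParams(a_plus=a_plus, alpha=alpha)
            for s in seeds:
                out = run_entrainment(cfg, stdp, seed=s, dt=dt)
                absolute = out["absolute"]
                if all(absolute["expected"]):
                    expected[ia, ip] += 1
                if any(absolute["unexpected"]):
                    unexpected[ia, ip] += 1
    expected /= reps
    unexpected /= reps
    return {
        "a_plus": list(a_plus_values),
        "alpha": list(alpha_values),
        "expected_fraction": expected,
        "unexpected_fraction": unexpected,
        "seeds": seeds,
    }
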