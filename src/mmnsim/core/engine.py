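"""Clock-driven integration engine.

Exponential-Euler update of the membrane equation

    Cm dV/dt = -g_leak (V - E_leak) - sum_c g_c(t) B_c(V) (V - E_c)
               + I_pulse(t) + I_noise(t)

with single-exponential conductance channels (AMPA, NMDA, GABA), the
sigmoidal magnesium factor on NMDA when enabled, threshold/reset
spiking, absolute refractoriness (V clamped at reset), transmission
delays via a circular pending-conductance buffer, release-fraction
short-term depression updated event-wise in closed form, and pair-based
STDP with lazily decayed per-neuron traces.

Internally: time in ms, voltage in mV, conductance in nS, capacitance
in pF, current in pA (so g*V is in pA and Cm/g_leak in ms).

Noise convention: each step draws an independent current with standard
deviation ``noise_sd * sqrt(0.1 / dt)`` so that the configured value is
the stationary per-step current SD at the default dt of 0.1 ms;
simulations at different dt then produce comparable voltage variance.

Synaptic transmission always incurs at least one time step of latency
(a zero-delay projection delivers at the next step).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .network import CompiledNetwork, CurrentPulse, NetworkSpec, compile_network
from .record import SpikeRecord

__all__ = ["integrate_network", "SimulationResult", "SimulationError"]

REF_DT = 0.1  # ms; anchor for the noise-scaling convention


class SimulationError(RuntimeError):
    pass


@njit(cache=True)
def _simulate(
    dt,
    n_steps,
    cm,
    g_leak,
    e_leak,
    v_th,
    v_reset,
    ref_steps,
    noise_sd,
    tau_syn,
    e_syn,
    mg_on,
    indptr,
    syn_post,
    syn_w,
    syn_rec,
    syn_delay,
    syn_pv,
    syn_taud,
    syn_d,
    syn_stdp,
    syn_pre,
    a_plus,
    a_minus,
    tau_a,
    w_min,
    w_max,
    rev_indptr,
    rev_syn,
    ev_step,
    ev_neuron,
    ev_damp,
    seed,
    max_spikes,
    v_rec_idx,
    v_rec_stride,
    snap_stride,
    syn_group,
    n_groups,
    efficacy_pv,
):
    np.random.seed(seed)
    n = cm.shape[0]
    n_syn = syn_post.shape[0]

    V = e_leak.copy()
    g = np.zeros((3, n))
    L = 2
    for k in range(n_syn):
        if syn_delay[k] + 1 > L:
            L = syn_delay[k] + 1
    pend = np.zeros((3, L, n))
    I_ext = np.zeros(n)
    ref_until = np.full(n, -1, dtype=np.int64)
    last_spike_t = np.full(n, -1e12)

    trace_pre = np.zeros(n)
    trace_pre_t = np.zeros(n)
    trace_post = np.zeros(n)
    trace_post_t = np.zeros(n)

    dec = np.empty(3)
    for c in range(3):
        dec[c] = np.exp(-dt / tau_syn[c])
    leak_fac = np.empty(n)
    for i in range(n):
        leak_fac[i] = np.exp(-g_leak[i] * dt / cm[i])

    spike_t = np.empty(max_spikes)
    spike_i = np.empty(max_spikes, dtype=np.int64)
    n_spk = 0
    overflow = 0

    n_vrec = v_rec_idx.shape[0]
    n_vrows = ((n_steps - 1) // v_rec_stride + 1) if (n_vrec > 0 and v_rec_stride > 0) else 1
    v_rec = np.zeros((n_vrows, max(n_vrec, 1)))
    n_srows = ((n_steps - 1) // snap_stride + 1) if (snap_stride > 0 and n_groups > 0) else 1
    w_snap = np.zeros((n_srows, max(n_groups, 1)))
    grp_count = np.zeros(max(n_groups, 1))
    if n_groups > 0:
        for k in range(n_syn):
            if syn_group[k] >= 0:
                grp_count[syn_group[k]] += 1.0

    spiked = np.empty(n, dtype=np.int64)
    ep = 0
    n_ev = ev_step.shape[0]

    for step in range(n_steps):
        t_next = (step + 1) * dt

        # deliver pending conductance jumps scheduled for this step
        sl = step % L
        for i in range(n):
            if pend[0, sl, i] != 0.0:
                g[0, i] += pend[0, sl, i]
                pend[0, sl, i] = 0.0
            if pend[1, sl, i] != 0.0:
                g[1, i] += pend[1, sl, i]
                pend[1, sl, i] = 0.0
            if pend[2, sl, i] != 0.0:
                g[2, i] += pend[2, sl, i]
                pend[2, sl, i] = 0.0

        # external square-pulse current edges
        while ep < n_ev and ev_step[ep] == step:
            I_ext[ev_neuron[ep]] += ev_damp[ep]
            ep += 1

        # integrate membrane and detect threshold crossings
        nsp = 0
        for i in range(n):
            if step < ref_until[i]:
                V[i] = v_reset[i]
                continue
            gA = g[0, i]
            gN = g[1, i]
            gG = g[2, i]
            Ii = I_ext[i]
            if noise_sd[i] > 0.0:
                Ii += noise_sd[i] * np.random.normal()
            if gA == 0.0 and gN == 0.0 and gG == 0.0:
                # pure leak: reuse the precomputed decay factor
                vinf = e_leak[i] + Ii / g_leak[i]
                V[i] = vinf + (V[i] - vinf) * leak_fac[i]
            else:
                if mg_on and gN != 0.0:
                    B = 1.0 / (1.0 + 0.28 * np.exp(-0.062 * V[i]))
                else:
                    B = 1.0
                gtot = g_leak[i] + gA + gN * B + gG
                num = (
                    g_leak[i] * e_leak[i]
                    + gA * e_syn[0]
                    + gN * B * e_syn[1]
                    + gG * e_syn[2]
                    + Ii
                )
                vinf = num / gtot
                V[i] = vinf + (V[i] - vinf) * np.exp(-gtot * dt / cm[i])
            if not np.isfinite(V[i]):
                return (
                    spike_t[:n_spk],
                    spike_i[:n_spk],
                    v_rec,
                    w_snap,
                    overflow,
                    i,
                    t_next,
                )
            if V[i] >= v_th[i]:
                spiked[nsp] = i
                nsp += 1
                V[i] = v_reset[i]
                ref_until[i] = step + ref_steps[i]
                if n_spk < max_spikes:
                    spike_t[n_spk] = t_next
                    spike_i[n_spk] = i
                    n_spk += 1
                else:
                    overflow = 1

        # decay conductances
        for i in range(n):
            g[0, i] *= dec[0]
            g[1, i] *= dec[1]
            g[2, i] *= dec[2]
            if g[0, i] < 1e-12:
                g[0, i] = 0.0
            if g[1, i] < 1e-12:
                g[1, i] = 0.0
            if g[2, i] < 1e-12:
                g[2, i] = 0.0

        # presynaptic phase: schedule transmission, then pre-trace updates.
        # Simultaneous pre/post events resolve pre-before-post.
        for s in range(nsp):
            i = spiked[s]
            for k in range(indptr[i], indptr[i + 1]):
                w_eff = syn_w[k]
                if syn_pv[k] > 0.0:
                    d = syn_d[k]
                    if last_spike_t[i] > -1e11:
                        d = 1.0 - (1.0 - d) * np.exp(
                            -(t_next - last_spike_t[i]) / syn_taud[k]
                        )
                    w_eff = w_eff * d
                    if efficacy_pv:
                        w_eff *= syn_pv[k]
                    syn_d[k] = d * (1.0 - syn_pv[k])
                pend[syn_rec[k], (step + syn_delay[k]) % L, syn_post[k]] += w_eff
                if syn_stdp[k]:
                    j = syn_post[k]
                    trace_post[j] *= np.exp(-(t_next - trace_post_t[j]) / tau_a)
                    trace_post_t[j] = t_next
                    wn = syn_w[k] + trace_post[j]
                    if wn < w_min:
                        wn = w_min
                    if wn > w_max:
                        wn = w_max
                    syn_w[k] = wn
            last_spike_t[i] = t_next
            trace_pre[i] *= np.exp(-(t_next - trace_pre_t[i]) / tau_a)
            trace_pre_t[i] = t_next
            trace_pre[i] += a_plus

        # postsynaptic phase
        for s in range(nsp):
            j = spiked[s]
            for r in range(rev_indptr[j], rev_indptr[j + 1]):
                k = rev_syn[r]
                i = syn_pre[k]
                trace_pre[i] *= np.exp(-(t_next - trace_pre_t[i]) / tau_a)
                trace_pre_t[i] = t_next
                wn = syn_w[k] + trace_pre[i]
                if wn < w_min:
                    wn = w_min
                if wn > w_max:
                    wn = w_max
                syn_w[k] = wn
            if rev_indptr[j + 1] > rev_indptr[j]:
                trace_post[j] *= np.exp(-(t_next - trace_post_t[j]) / tau_a)
                trace_post_t[j] = t_next
                trace_post[j] += a_minus

        # recordings
        if n_vrec > 0 and v_rec_stride > 0 and step % v_rec_stride == 0:
            row = step // v_rec_stride
            for c in range(n_vrec):
                v_rec[row, c] = V[v_rec_idx[c]]
        if snap_stride > 0 and n_groups > 0 and step % snap_stride == 0:
            row = step // snap_stride
            for k in range(n_syn):
                gd = syn_group[k]
                if gd >= 0:
                    w_snap[row, gd] += syn_w[k]
            for gd in range(n_groups):
                if grp_count[gd] > 0:
                    w_snap[row, gd] /= grp_count[gd]

    return spike_t[:n_spk], spike_i[:n_spk], v_rec, w_snap, overflow, -1, 0.0


@dataclass
class SimulationResult:
    record: SpikeRecord
    overflow: bool = False
    v_trace_times: Optional[np.ndarray] = None
    v_traces: Optional[np.ndarray] = None            # (n_rows, n_recorded)
    weight_times: Optional[np.ndarray] = None
    weight_snapshots: Optional[np.ndarray] = None    # (n_rows, n_groups)
    final_weights: Optional[np.ndarray] = None


def _build_events(
    net: CompiledNetwork, inputs: Sequence[CurrentPulse], dt: float, n_steps: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    steps: List[int] = []
    neurons: List[int] = []
    damps: List[float] = []
    for pulse in inputs:
        s0 = int(round(pulse.t_start / dt))
        s1 = int(round(pulse.t_end / dt))
        if s0 >= n_steps or s1 <= 0 or s1 == s0:
            continue
        amp = pulse.amplitude * 1000.0  # nA -> pA
        if pulse.neuron is None:
            idxs = range(net.offsets[pulse.population], net.offsets[pulse.population] + net.sizes[pulse.population])
        else:
            idxs = [net.global_index(pulse.population, pulse.neuron)]
        for gi in idxs:
            steps.append(max(s0, 0))
            neurons.append(gi)
            damps.append(amp)
            if s1 < n_steps:
                steps.append(s1)
                neurons.append(gi)
                damps.append(-amp)
    if not steps:
        return (
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            np.empty(0),
        )
    order = np.argsort(np.asarray(steps), kind="stable")
    return (
        np.asarray(steps, dtype=np.int64)[order],
        np.asarray(neurons, dtype=np.int64)[order],
        np.asarray(damps, dtype=float)[order],
    )


def integrate_network(
    spec: NetworkSpec,
    inputs: Sequence[CurrentPulse],
    duration: float,
    dt: float = 0.1,
    seed: int = 0,
    *,
    compiled: Optional[CompiledNetwork] = None,
    record_v: Optional[Sequence[Tuple[str, int]]] = None,
    v_stride: int = 1,
    stdp: Optional[Dict] = None,
    syn_groups: Optional[Dict[str, int]] = None,
    snapshot_interval: float = 0.0,
    max_spikes: int = 4_000_000,
) -> SimulationResult:
    """Integrate the network and return the spikes (plus optional traces).

    Parameters
    ----------
    spec, inputs, duration, dt, seed
        The network description, square-pulse schedule, simulated time
        (ms), time step (ms) and noise RNG seed.  Identical arguments
        produce bit-identical results.
    record_v
        Optional list of ``(population, neuron_index)`` whose membrane
        potential is sampled every ``v_stride`` steps.
    stdp
        Optional dict with keys ``a_plus, a_minus, tau_a, w_min, w_max``
        governing all projections flagged ``plastic=True``.
    syn_groups / snapshot_interval
        Group-tagged synapses have their mean weight recorded every
        ``snapshot_interval`` ms.
    """
    if dt <= 0:
        raise SimulationError("dt must be positive")
    n_steps = int(round(duration / dt))
    net = compiled if compiled is not None else compile_network(spec, syn_groups)

    ev_step, ev_neuron, ev_damp = _build_events(net, inputs, dt, n_steps)

    delay_steps = np.maximum(np.round(net.syn_delay_ms / dt).astype(np.int64), 1)
    syn_d = np.ones(len(net.syn_w))
    syn_w = net.syn_w.copy()

    if stdp is None:
        a_plus, a_minus, tau_a = 0.0, 0.0, 20.0
        w_min, w_max = 0.0, np.inf
    else:
        a_plus = float(stdp["a_plus"])
        a_minus = float(stdp["a_minus"])
        tau_a = float(stdp.get("tau_a", 20.0))
        w_min = float(stdp.get("w_min", 0.0))
        w_max = float(stdp.get("w_max", 2.4))

    if record_v:
        v_idx = np.array(
            [net.global_index(p, i) for p, i in record_v], dtype=np.int64
        )
        v_stride_eff = max(int(v_stride), 1)
    else:
        v_idx = np.empty(0, dtype=np.int64)
        v_stride_eff = 0

    n_groups = 0
    snap_stride = 0
    if syn_groups and snapshot_interval > 0:
        n_groups = max(syn_groups.values()) + 1
        snap_stride = max(int(round(snapshot_interval / dt)), 1)

    noise_scaled = net.noise_sd * np.sqrt(REF_DT / dt)
    ref_steps = np.maximum(np.round(net.t_ref / dt).astype(np.int64), 1)

    (
        spike_t,
        spike_i,
        v_rec,
        w_snap,
        overflow,
        bad_neuron,
        bad_t,
    ) = _simulate(
        dt,
        n_steps,
        net.cm,
        net.g_leak,
        net.e_leak,
        net.v_th,
        net.v_reset,
        ref_steps,
        noise_scaled,
        net.tau_syn,
        net.e_syn,
        net.mg_on,
        net.indptr,
        net.syn_post,
        syn_w,
        net.syn_rec,
        delay_steps,
        net.syn_pv,
        net.syn_taud,
        syn_d,
        net.syn_stdp,
        net.syn_pre,
        a_plus,
        a_minus,
        tau_a,
        w_min,
        w_max,
        net.rev_indptr,
        net.rev_syn,
        ev_step,
        ev_neuron,
        ev_damp,
        seed,
        max_spikes,
        v_idx,
        v_stride_eff,
        snap_stride,
        net.syn_group,
        n_groups,
        spec.efficacy_includes_pv,
    )

    if bad_neuron >= 0:
        pid = int(net.pop_of(np.array([bad_neuron]))[0])
        pname = spec.populations[pid].name
        local = bad_neuron - net.offsets[pname]
        raise SimulationError(
            f"non-finite membrane potential for neuron {local} of population "
            f"{pname} at t={bad_t:.3f} ms (unstable parameters?)"
        )

    pop_bounds = np.array([net.offsets[p.name] for p in spec.populations])
    pop_ids = np.searchsorted(pop_bounds, spike_i, side="right") - 1
    local_idx = spike_i - pop_bounds[pop_ids]
    record = SpikeRecord(
        times=spike_t,
        neurons=local_idx,
        pop_ids=pop_ids,
        populations=[p.name for p in spec.populations],
        pop_sizes=[p.n for p in spec.populations],
        t_end=n_steps * dt,
        seed=seed,
    )

    result = SimulationResult(record=record, overflow=bool(overflow))
    if len(v_idx):
        rows = v_rec.shape[0]
        result.v_trace_times = (np.arange(rows) * v_stride_eff) * dt
        result.v_traces = v_rec
    if n_groups:
        rows = w_snap.shape[0]
        result.weight_times = (np.arange(rows) * snap_stride) * dt
        result.weight_snapshots = w_snap
    result.final_weights = syn_w
    return result
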