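"""Integration engine against analytic LIF oracles."""

import numpy as np
import pytest

from mmnsim.core import (
    CurrentPulse,
    DepressionParams,
    NeuronParams,
    NetworkSpec,
    PopulationSpec,
    ProjectionSpec,
    SimulationError,
    SynapseKinetics,
    integrate_network,
)


def lif_isi(neuron: NeuronParams, current_nA: float) -> float:
    drive = current_nA * 1000.0 / neuron.g_leak
    tau = neuron.cm / neuron.g_leak
    return neuron.t_ref + tau * np.log(
        (drive - (neuron.v_reset - neuron.e_leak))
        / (drive - (neuron.v_thresh - neuron.e_leak))
    )


def test_resting_fixed_point(single_neuron_spec):
    res = integrate_network(single_neuron_spec, [], 200.0, record_v=[("A", 0)])
    assert len(res.record) == 0
    assert np.allclose(res.v_traces[:, 0], -70.0)


def test_subthreshold_steady_state(single_neuron_spec):
    # I/g_leak = 15 mV -> V -> -55 mV, no spikes
    res = integrate_network(
        single_neuron_spec,
        [CurrentPulse("A", 0.0, 1000.0, 0.15)],
        1000.0,
        record_v=[("A", 0)],
    )
    assert len(res.record) == 0
    assert res.v_traces[-1, 0] == pytest.approx(-55.0, abs=0.02)


@pytest.mark.parametrize("current", [0.25, 0.3, 0.5])
def test_suprathreshold_isi_matches_analytic(single_neuron_spec, current):
    dt = 0.1
    res = integrate_network(
        single_neuron_spec, [CurrentPulse("A", 0.0, 3000.0, current)], 3000.0, dt=dt
    )
    isis = np.diff(res.record.times)
    expected = lif_isi(NeuronParams(), current)
    assert np.all(np.abs(isis - expected) <= 2 * dt)


def test_halving_dt_shifts_spike_timing_less_than_dt(single_neuron_spec):
    # first-spike time and every interspike interval move by < dt when
    # the step is halved (absolute times accumulate the per-ISI shift)
    pulses = [CurrentPulse("A", 0.0, 1000.0, 0.3)]
    t1 = integrate_network(single_neuron_spec, pulses, 1000.0, dt=0.1).record.times
    t2 = integrate_network(single_neuron_spec, pulses, 1000.0, dt=0.05).record.times
    n = min(len(t1), len(t2))
    assert n > 10
    assert abs(t1[0] - t2[0]) < 0.1 + 1e-9
    assert np.all(np.abs(np.diff(t1[:n]) - np.diff(t2[:n])) < 0.1 + 1e-9)


def test_bit_reproducibility():
    pop = PopulationSpec("A", 20, noise_sd=0.2)
    spec = NetworkSpec([pop])
    pulses = [CurrentPulse("A", 0.0, 500.0, 0.25)]
    a = integrate_network(spec, pulses, 500.0, seed=5)
    b = integrate_network(spec, pulses, 500.0, seed=5)
    c = integrate_network(spec, pulses, 500.0, seed=6)
    assert np.array_equal(a.record.times, b.record.times)
    assert np.array_equal(a.record.neurons, b.record.neurons)
    assert not np.array_equal(a.record.times, c.record.times)


def _two_pop_spec(depression):
    pre = PopulationSpec("pre", 10)
    post = PopulationSpec("post", 10)
    proj = ProjectionSpec(
        "pre", "post", 1.0, [SynapseKinetics("AMPA", 4.0)],
        depression=depression, seed=3,
    )
    return NetworkSpec([pre, post], [proj])


def test_identical_stimuli_without_depression_give_identical_responses():
    # pv -> 0 limit handled as D = 1: the second tone evokes the same
    # response pattern as the first (deterministic network, no noise)
    spec = _two_pop_spec(depression=None)
    pulses = [
        CurrentPulse("pre", 100.0, 150.0, 0.3),
        CurrentPulse("pre", 600.0, 650.0, 0.3),
    ]
    res = integrate_network(spec, pulses, 1100.0)
    t, idx = res.record.population("post")
    first = sorted(zip(np.round(t[(t >= 100) & (t < 500)] - 100, 6), idx[(t >= 100) & (t < 500)]))
    second = sorted(zip(np.round(t[(t >= 600) & (t < 1000)] - 600, 6), idx[(t >= 600) & (t < 1000)]))
    assert len(first) > 0
    assert first == second


def test_depression_weakens_repeated_responses():
    spec = _two_pop_spec(DepressionParams(pv=0.5, tau_d=5000.0))
    pulses = [
        CurrentPulse("pre", 100.0, 150.0, 0.3),
        CurrentPulse("pre", 600.0, 650.0, 0.3),
    ]
    res = integrate_network(spec, pulses, 1100.0)
    t, _ = res.record.population("post")
    n_first = np.count_nonzero((t >= 100) & (t < 500))
    n_second = np.count_nonzero((t >= 600) & (t < 1000))
    assert n_second < n_first


def test_unstable_parameters_raise_named_error(single_neuron_spec):
    with pytest.raises(SimulationError, match="population A"):
        integrate_network(
            single_neuron_spec, [CurrentPulse("A", 0.0, 10.0, float("inf"))], 10.0
        )


def test_transmission_delay_shifts_arrival():
    def first_post_spike(delay):
        pre = PopulationSpec("pre", 20)
        post = PopulationSpec("post", 20)
        proj = ProjectionSpec(
            "pre", "post", 1.0, [SynapseKinetics("AMPA", 1.5)], delay=delay, seed=0
        )
        spec = NetworkSpec([pre, post], [proj])
        res = integrate_network(spec, [CurrentPulse("pre", 0.0, 50.0, 0.3)], 100.0)
        t, _ = res.record.population("post")
        return t.min()

    t0 = first_post_spike(0.0)
    t5 = first_post_spike(5.0)
    assert t5 - t0 == pytest.approx(5.0, abs=0.2)


def test_nmda_voltage_block_reduces_drive_at_rest():
    def post_spikes(mg_block):
        pre = PopulationSpec("pre", 20)
        post = PopulationSpec("post", 20)
        proj = ProjectionSpec(
            "pre", "post", 1.0,
            [SynapseKinetics("NMDA", 1.0, mg_block=mg_block)], seed=0,
        )
        spec = NetworkSpec([pre, post], [proj], nmda_mg_block=mg_block)
        res = integrate_network(spec, [CurrentPulse("pre", 0.0, 100.0, 0.3)], 300.0)
        t, _ = res.record.population("post")
        return len(t)

    assert post_spikes(False) > post_spikes(True)
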