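"""Excitability mapping, perturbations, and the synthetic cohort."""

import numpy as np
import pytest

from mmnsim.core import NeuronParams
from mmnsim.core.params import ParameterError
from mmnsim.mmn import REFERENCE_PARAMS, build_mmn_network
from mmnsim.scz import (
    CorticalOutputParams,
    analytic_lif_rate,
    apply_perturbation,
    attach_cortical_output,
    capacitance_from_auc,
    fi_curve,
    fit_cortical_output,
    synthesize_subject_aucs,
)

CO_NEURON = NeuronParams(cm=580.0, g_leak=4.0, v_thresh=-58.0, v_reset=-60.0,
                         t_ref=10.0)


class TestFICurve:
    def test_subthreshold_currents_give_zero_auc(self):
        fc = fi_curve(NeuronParams(), currents=[0.0, 0.05, 0.1], duration=2000.0,
                      settle=200.0)
        assert np.all(fc.rates == 0.0)
        assert fc.auc == 0.0

    def test_matches_analytic_rate_within_two_percent(self):
        neuron = NeuronParams()
        fc = fi_curve(neuron, duration=4000.0, settle=500.0)
        for c, r in zip(fc.currents, fc.rates):
            expected = analytic_lif_rate(neuron, c)
            if expected == 0.0:
                assert r == 0.0
            else:
                assert r == pytest.approx(expected, rel=0.02)

    def test_default_current_protocol(self):
        fc = fi_curve(NeuronParams(), duration=1200.0, settle=200.0)
        assert np.allclose(fc.currents, np.arange(0.0, 1.01, 0.1))

    def test_auc_decreases_with_capacitance(self):
        aucs = []
        for cm in [300.0, 450.0, 600.0, 750.0]:
            fc = fi_curve(CO_NEURON.with_cm(cm), duration=3000.0, settle=500.0)
            aucs.append(fc.auc)
        assert np.all(np.diff(aucs) < 0)


class TestCapacitanceFromAuc:
    def test_equal_auc_gives_unit_scale(self):
        assert capacitance_from_auc(10.0, 10.0) == pytest.approx(1.0)

    def test_printed_percentage_pairs(self):
        # AUC 6.7% below reference -> +7.2% capacitance; 16.1% -> +19.2%
        assert capacitance_from_auc(1.0 - 0.067, 1.0) == pytest.approx(1.072, abs=2e-3)
        assert capacitance_from_auc(1.0 - 0.161, 1.0) == pytest.approx(1.192, abs=2e-3)

    def test_squared_exponent_available(self):
        scale = capacitance_from_auc(0.9, 1.0, exponent=2.0)
        assert scale == pytest.approx((1 / 0.9) ** 2)

    def test_fit_round_trip_recovers_capacitance(self):
        target_cm = 640.0
        target = fi_curve(CO_NEURON.with_cm(target_cm), duration=4000.0,
                          settle=500.0).auc
        cm = capacitance_from_auc(
            target, auc_ref=None, method="fit", neuron=CO_NEURON,
            fit_duration=4000.0, fit_settle=500.0,
        )
        assert cm == pytest.approx(target_cm, rel=0.01)

    def test_ratio_and_fit_agree_for_small_perturbations(self):
        # rate ~ 1/Cm holds when the refractory time is a small fraction
        # of the interspike interval; use a short-t_ref variant for the
        # near-linearity check
        neuron = NeuronParams(cm=580.0, g_leak=4.0, t_ref=0.5)
        auc_ref = fi_curve(neuron, duration=4000.0, settle=500.0).auc
        for rel in (0.93, 0.84):
            auc_i = auc_ref * rel
            scale = capacitance_from_auc(auc_i, auc_ref)
            cm_fit = capacitance_from_auc(
                auc_i, None, method="fit", neuron=neuron,
                fit_duration=4000.0, fit_settle=500.0,
            )
            assert cm_fit / neuron.cm == pytest.approx(scale, rel=0.05)

    def test_long_refractory_discrepancy_is_visible_not_hidden(self):
        # with t_ref = 10 ms the proportionality degrades; the fit method
        # reports the larger true capacitance change
        auc_ref = fi_curve(CO_NEURON, duration=4000.0, settle=500.0).auc
        auc_i = auc_ref * 0.84
        scale = capacitance_from_auc(auc_i, auc_ref)
        cm_fit = capacitance_from_auc(
            auc_i, None, method="fit", neuron=CO_NEURON,
            fit_duration=4000.0, fit_settle=500.0,
        )
        assert cm_fit / CO_NEURON.cm > scale

    def test_unbracketed_fit_errors(self):
        with pytest.raises(ParameterError, match="bracket"):
            capacitance_from_auc(1e9, None, method="fit", neuron=CO_NEURON,
                                 fit_duration=1500.0, fit_settle=500.0)


class TestPerturbation:
    def test_unit_magnitude_is_identity(self):
        net = build_mmn_network(REFERENCE_PARAMS, seed=0)
        pert = apply_perturbation(net, "capacitance_scale", 1.0)
        for a, b in zip(net.populations, pert.populations):
            assert np.array_equal(a.cm_values, b.cm_values)
        pert = apply_perturbation(net, "excitatory_conductance_scale", 1.0)
        for a, b in zip(net.projections, pert.projections):
            assert [k.g_max for k in a.kinetics] == [k.g_max for k in b.kinetics]

    def test_capacitance_scale_targets_excitatory_by_default(self):
        net = build_mmn_network(REFERENCE_PARAMS, seed=0)
        pert = apply_perturbation(net, "capacitance_scale", 1.2)
        for a, b in zip(net.populations, pert.populations):
            factor = 1.2 if a.excitatory else 1.0
            assert np.allclose(b.cm_values, a.cm_values * factor)

    def test_conductance_scale_leaves_gaba_untouched(self):
        net = build_mmn_network(REFERENCE_PARAMS, seed=0)
        pert = apply_perturbation(net, "excitatory_conductance_scale", 0.81)
        for a, b in zip(net.projections, pert.projections):
            for ka, kb in zip(a.kinetics, b.kinetics):
                if ka.receptor == "GABA":
                    assert kb.g_max == ka.g_max
                else:
                    assert kb.g_max == pytest.approx(ka.g_max * 0.81)

    def test_unknown_target_rejected(self):
        net = build_mmn_network(REFERENCE_PARAMS, seed=0)
        with pytest.raises(ParameterError):
            apply_perturbation(net, "capacitance_scale", 1.1, targets=["XX"])
        with pytest.raises(ParameterError):
            apply_perturbation(net, "bogus_kind", 1.1)


class TestCorticalOutput:
    def test_attach_adds_population_and_projection(self):
        net = build_mmn_network(REFERENCE_PARAMS, seed=0)
        co = CorticalOutputParams()
        full = attach_cortical_output(net, co, seed=0)
        assert "CO" in full.names
        assert full.population("CO").n == 40
        eo_co = [p for p in full.projections if p.source == "EO" and p.target == "CO"]
        assert len(eo_co) == 1
        assert eo_co[0].kinetics[0].g_max == pytest.approx(3000.0)

    def test_silent_without_noise_and_input(self):
        from mmnsim.core import integrate_network

        net = build_mmn_network(REFERENCE_PARAMS, seed=0)
        co = CorticalOutputParams(noise_sd=0.0, g_ampa_from_eo=1e-6)
        full = attach_cortical_output(net, co, seed=0)
        res = integrate_network(full, [], 2000.0, seed=0)
        t, _ = res.record.population("CO")
        assert len(t) == 0

    def test_spontaneous_rate_increases_with_noise(self):
        from mmnsim.core import integrate_network, NetworkSpec, PopulationSpec

        rates = []
        for noise in (1.0, 1.75, 2.5):
            pop = PopulationSpec(
                "CO", 40, neuron=CO_NEURON, noise_sd=noise
            ).sample_cm(0.3, 1)
            res = integrate_network(NetworkSpec([pop]), [], 5000.0, seed=2)
            rates.append(len(res.record) / 40 / 5.0)
        assert rates[0] < rates[1] < rates[2]


class TestFitCorticalOutput:
    def test_degenerate_single_cell(self):
        g, n, table = fit_cortical_output(
            lambda g, n: (8.0, 20.0), (8.0, 20.0), [3000.0], [1.75]
        )
        assert (g, n) == (3000.0, 1.75)
        assert len(table) == 1

    def test_planted_optimum_recovered(self):
        def run_rates(g, noise):
            # synthetic response surface with a unique best cell
            return 8.0 + 2 * abs(g - 3000.0) / 1000.0, 20.0 - abs(noise - 1.75)

        g, n, table = fit_cortical_output(
            run_rates, (8.0, 20.0),
            [1000.0, 2000.0, 3000.0, 4000.0], [1.0, 1.75, 2.5],
        )
        assert g == 3000.0
        assert n == 1.75

    def test_empty_grid_rejected(self):
        with pytest.raises(ParameterError):
            fit_cortical_output(lambda g, n: (0, 0), (8, 20), [], [1.0])


class TestSyntheticCohort:
    def test_zero_reduction_matches_group_means(self):
        table = synthesize_subject_aucs(300, 300, 0.0, seed=1)
        ctrl = table[table.group == "CTRL"].auc_norm
        scz = table[table.group == "SCZ"].auc_norm
        assert ctrl.mean() == pytest.approx(1.0, abs=1e-12)
        assert scz.mean() == pytest.approx(1.0, abs=0.05)

    def test_mean_reduction_161(self):
        table = synthesize_subject_aucs(200, 200, 0.161, seed=2)
        scz = table[table.group == "SCZ"].auc_norm
        assert 0.82 <= scz.mean() <= 0.86

    @pytest.mark.parametrize("reduction", [0.067, 0.161])
    def test_default_reductions_supported(self, reduction):
        table = synthesize_subject_aucs(100, 100, reduction, seed=3)
        scz = table[table.group == "SCZ"].auc_norm
        assert scz.mean() == pytest.approx(1.0 - reduction, abs=0.05)

    def test_reproducible_and_positive(self):
        a = synthesize_subject_aucs(50, 50, 0.1, seed=9)
        b = synthesize_subject_aucs(50, 50, 0.1, seed=9)
        assert a.equals(b)
        assert (a.auc_norm > 0).all()

    def test_invalid_args(self):
        with pytest.raises(ParameterError):
            synthesize_subject_aucs(0, 10, 0.1)
        with pytest.raises(ParameterError):
            synthesize_subject_aucs(10, 10, 1.0)
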