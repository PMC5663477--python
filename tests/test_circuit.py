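"""Tests for the LIF circuit model: conductance calibration, network
construction, trial dynamics and the perturbation rules."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from popcircuit.circuit import (StimulusProtocol, build_network,
                                fit_response_curves, psp_to_conductance,
                                relax_voltages, response_curve, run_trial)
from popcircuit.params import (CELL_TYPES, ZERO_CONNECTIONS, default_params,
                               perturb_params, sweep_parameter_names)


class TestPspToConductance:
    def test_zero_psp_zero_conductance(self, tiny_circuit):
        assert psp_to_conductance(0.0, "E", "e", tiny_circuit) == 0.0

    def test_linearity(self, tiny_circuit):
        g1 = psp_to_conductance(0.5, "E", "e", tiny_circuit)
        g2 = psp_to_conductance(1.0, "E", "e", tiny_circuit)
        assert g2 == pytest.approx(2 * g1)

    @pytest.mark.parametrize("post,kind,psp", [
        ("E", "e", 0.5), ("Ipv", "e", 0.8), ("E", "i", 0.4), ("Ipv", "i", 0.5),
    ])
    def test_matches_ode_integration(self, tiny_circuit, post, kind, psp):
        # integrate the linearized single-synapse membrane equation and
        # check the voltage peak equals the requested PSP within 1%
        c = tiny_circuit.cells[post]
        g = psp_to_conductance(psp, post, kind, tiny_circuit)
        if kind == "e":
            driving = tiny_circuit.erev_e - c.vrest
            tausyn = c.tausyn_e
        else:
            driving = -55.0 - c.erev_i
            tausyn = c.tausyn_i

        def rhs(t, v):
            return (g * np.exp(-t / tausyn) * driving - v) / c.taum

        sol = solve_ivp(rhs, [0, 300], [0.0], max_step=0.05,
                        dense_output=True)
        peak = np.abs(sol.y[0]).max()
        assert peak == pytest.approx(psp, rel=0.01)

    def test_alpha_function_limit(self, tiny_circuit):
        # tausyn == taum: degenerate bi-exponential falls back to the
        # alpha-function peak instead of dividing by zero
        p = tiny_circuit.copy()
        p.cells["E"].tausyn_e = p.cells["E"].taum
        g = psp_to_conductance(0.5, "E", "e", p)
        expected = 0.5 / ((p.erev_e - p.cells["E"].vrest) / np.e)
        assert g == pytest.approx(expected, rel=1e-9)

    def test_rejects_negative_psp(self, tiny_circuit):
        with pytest.raises(ValueError):
            psp_to_conductance(-0.5, "E", "e", tiny_circuit)


class TestBuildNetwork:
    def test_absent_classes_have_no_synapses(self, tiny_circuit):
        net = build_network(tiny_circuit, seed=0)
        for pair in ZERO_CONNECTIONS:
            assert net.class_counts.get(pair, 0) == 0

    def test_synapse_count_binomial_and_lognormal_median(self):
        params = default_params(scale=0.5, scale_compensate=False)
        net = build_network(params, seed=1)
        n_e = params.n_of("E")
        p = params.connections[("E", "E")].pcon
        n_pairs = n_e * (n_e - 1)
        expected = p * n_pairs
        sd = np.sqrt(n_pairs * p * (1 - p))
        assert abs(net.class_counts[("E", "E")] - expected) < 4 * sd
        # sample median of E->E amplitudes near the configured 0.2 mV
        amps = []
        e_slice = net.type_slices["E"]
        for pre in range(net.n_l4, net.n_l4 + n_e):
            for s in range(net.indptr[pre], net.indptr[pre + 1]):
                t = net.targets[s]
                if e_slice.start <= t < e_slice.stop and not net.inh[s]:
                    amps.append(net.amp_mv[s])
        assert np.median(amps) == pytest.approx(0.2, rel=0.05)

    def test_mean_equals_median_collapses_spread(self, tiny_circuit):
        p = tiny_circuit.copy()
        conn = p.connections[("EL4", "E")]
        conn.w_mean = conn.w_median = 0.5
        net = build_network(p, seed=2)
        el4e = [net.amp_mv[s] for pre in range(net.n_l4)
                for s in range(net.indptr[pre], net.indptr[pre + 1])
                if net.targets[s] < net.type_slices["E"].stop]
        assert np.allclose(el4e, 0.5)

    def test_no_self_synapses(self, tiny_circuit):
        net = build_network(tiny_circuit, seed=3)
        for pre in range(net.n_l4, net.n_l4 + net.n_l23):
            post_of_pre = pre - net.n_l4
            for s in range(net.indptr[pre], net.indptr[pre + 1]):
                assert net.targets[s] != post_of_pre

    def test_amplitudes_capped(self, small_circuit):
        net = build_network(small_circuit, seed=4)
        assert net.amp_mv.max() <= small_circuit.psp_cap + 1e-12

    def test_seed_determinism(self, tiny_circuit):
        n1 = build_network(tiny_circuit, seed=5)
        n2 = build_network(tiny_circuit, seed=5)
        assert np.array_equal(n1.g, n2.g)
        assert np.array_equal(n1.targets, n2.targets)

    def test_mean_below_median_rejected(self, tiny_circuit):
        p = tiny_circuit.copy()
        p.connections[("E", "E")].w_mean = 0.1   # below the 0.2 median
        with pytest.raises(ValueError):
            p.validate()


class TestRunTrial:
    def test_no_drive_no_spikes(self, small_circuit):
        net = build_network(small_circuit, seed=0)
        spiked = run_trial(net, np.array([], dtype=int), small_circuit, seed=1)
        assert spiked.sum() == 0

    def test_saturating_drive_activates_excitatory_cells(self, small_circuit):
        p = small_circuit.copy()
        conn = p.connections[("EL4", "E")]
        conn.prel = 1.0
        conn.w_mean, conn.w_median = 6.0, 5.5
        net = build_network(p, seed=0)
        spiked = run_trial(net, np.arange(net.n_l4), p, seed=1)
        e_mask = net.type_codes == 0
        assert spiked[e_mask].mean() > 0.9

    def test_passive_relaxation_matches_closed_form(self, small_circuit):
        net = build_network(small_circuit, seed=0)
        tc = net.type_codes
        vrest = np.array([small_circuit.cells[t].vrest for t in CELL_TYPES])[tc]
        taum = np.array([small_circuit.cells[t].taum for t in CELL_TYPES])[tc]
        v0 = vrest + 10.0
        duration = 20.0
        v_end = relax_voltages(net, small_circuit, v0, duration)
        expected = vrest + 10.0 * np.exp(-duration / taum)
        # forward-Euler truncation error at dt = 0.01 ms is far below 1e-3 mV
        assert np.allclose(v_end, expected, atol=1e-3)

    def test_seeded_trial_determinism(self, small_circuit):
        net = build_network(small_circuit, seed=0)
        active = np.arange(0, net.n_l4, 2)
        s1 = run_trial(net, active, small_circuit, seed=9)
        s2 = run_trial(net, active, small_circuit, seed=9)
        assert np.array_equal(s1, s2)

    def test_rejects_bad_l4_indices(self, small_circuit):
        net = build_network(small_circuit, seed=0)
        with pytest.raises(ValueError):
            run_trial(net, np.array([net.n_l4 + 3]), small_circuit, seed=0)


@pytest.fixture(scope="module")
def resp(small_circuit):
    net = build_network(small_circuit, seed=2)
    proto = StimulusProtocol(l4_fractions=np.linspace(0, 1, 6),
                             n_permutations=5, n_release_repeats=5,
                             seed=3)
    return net, response_curve(net, proto, small_circuit)


class TestResponseCurve:
    def test_zero_fraction_silent(self, resp):
        _, r = resp
        assert np.all(r.q[:, 0] == 0)

    def test_probabilities_valid(self, resp):
        _, r = resp
        assert r.q.min() >= 0 and r.q.max() <= 1

    def test_mean_e_response_monotone(self, resp):
        _, r = resp
        mean_e = r.for_type("E").mean(axis=0)
        # non-decreasing up to binomial noise on 25-trial estimates
        assert np.all(np.diff(mean_e) > -0.02)

    def test_5ht_cells_respond_without_direct_drive(self):
        # 5HT3aR cells receive no L4 synapses yet respond at strong drive,
        # via disynaptic excitation from L2/3 E cells; the effect needs the
        # full-size circuit, so probe a single strong stimulation level
        params = default_params(scale=1.0)
        net = build_network(params, seed=2)
        assert net.class_counts[("EL4", "I5ht")] == 0
        proto = StimulusProtocol(l4_fractions=np.array([0.0, 1.0]),
                                 n_permutations=5, n_release_repeats=5, seed=3)
        r = response_curve(net, proto, params)
        assert r.for_type("I5ht")[:, 1].max() > 0

    def test_fit_response_curves_returns_fits(self, resp):
        _, r = resp
        fits = fit_response_curves(r)
        assert len(fits) == r.q.shape[0]
        valid = [f for f in fits if f.valid]
        assert len(valid) > 0
        assert all(f.domain == "l4_fraction" for f in fits)


class TestPerturbParams:
    def test_multiplicative_release_probability(self, tiny_circuit):
        p = perturb_params(tiny_circuit, "prel_EE", +0.2)
        assert p.connections[("E", "E")].prel == pytest.approx(0.30)

    def test_weight_pair_moves_in_tandem(self, tiny_circuit):
        p = perturb_params(tiny_circuit, "w_EE", +0.2)
        conn = p.connections[("E", "E")]
        assert conn.w_mean == pytest.approx(0.444)
        assert conn.w_median == pytest.approx(0.24)

    def test_vrest_moves_toward_threshold(self, tiny_circuit):
        p = perturb_params(tiny_circuit, "Vrest_E", +0.2)
        # -68 moved 20% of the 30 mV gap toward -38
        assert p.cells["E"].vrest == pytest.approx(-62.0)

    def test_vth_moves_away_from_rest(self, tiny_circuit):
        p = perturb_params(tiny_circuit, "Vth_E", +0.2)
        assert p.cells["E"].vth == pytest.approx(-32.0)

    def test_excitatory_reversal_scales_distance_from_rest(self, tiny_circuit):
        p = perturb_params(tiny_circuit, "Erev_e", +0.2)
        assert p.erev_e == pytest.approx(-68.0 + 1.2 * 68.0)

    def test_inhibitory_reversal_scales_distance_from_vth(self, tiny_circuit):
        p = perturb_params(tiny_circuit, "Erev_E_i", -0.2)
        vth = tiny_circuit.cells["E"].vth
        erev = tiny_circuit.cells["E"].erev_i
        assert p.cells["E"].erev_i == pytest.approx(vth + 0.8 * (erev - vth))

    def test_probability_clamped_with_warning(self, tiny_circuit, caplog):
        p = tiny_circuit.copy()
        p.connections[("E", "Ipv")].pcon = 0.9
        out = perturb_params(p, "pcon_EIpv", +0.2)
        assert out.connections[("E", "Ipv")].pcon == 1.0

    def test_null_perturbation_identity(self, tiny_circuit):
        p = perturb_params(tiny_circuit, None, +0.2)
        assert p.to_dict() == tiny_circuit.to_dict()

    def test_excluded_parameters_rejected(self, tiny_circuit):
        for bad in ("tref_E", "pcon_IsomIsom", "pcon_EL4I5ht"):
            with pytest.raises(KeyError):
                perturb_params(tiny_circuit, bad, +0.2)

    def test_sweep_list_has_76_parameters(self):
        names = sweep_parameter_names()
        assert len(names) == 76
        assert len(set(names)) == 76
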