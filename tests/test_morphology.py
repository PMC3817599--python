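"""Morphology invariants, serialization, cable equation and currents."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import gliosim as gs
from gliosim.channels import V_REST
from gliosim.morphology import (Compartment, MembraneState, Morphology,
                                cable_rhs, transmembrane_currents)
from tests.conftest import passive_pair


class TestBuildMorphology:
    def test_ca3_has_21_compartments(self, ca3_morph):
        assert ca3_morph.n == 21
        assert sum(c.role_tag == "soma" for c in ca3_morph.compartments) == 1

    def test_ca1_has_23_compartments_with_spines_at_original_6_and_12(self, ca1_morph):
        assert ca1_morph.n == 23
        spines = [c for c in ca1_morph.compartments if c.role_tag == "spine_head"]
        assert len(spines) == 2
        # original numbering: soma = 9; 6th -> 3 basal steps out; 12th -> 3 apical
        basal, apical = ca1_morph.spine_positions
        assert ca1_morph.compartments[basal].role_tag == "basal_dendrite"
        assert ca1_morph.compartments[apical].role_tag == "apical_dendrite"
        assert basal == 3 and apical == 11

    def test_ca1_has_one_is_and_one_axon_both_lfp_excluded(self, ca1_morph):
        roles = [c.role_tag for c in ca1_morph.compartments]
        assert roles.count("IS") == 1 and roles.count("axon") == 1
        from gliosim.morphology import LFP_EXCLUDED_ROLES
        assert set(LFP_EXCLUDED_ROLES) == {"IS", "axon"}

    def test_unknown_cell_type_rejected(self):
        with pytest.raises(ValueError, match="unknown cell_type"):
            gs.build_morphology("CA2")

    def test_tree_structure_enforced(self):
        c0 = Compartment(0, None, 10.0, 1.0, "soma")
        c1 = Compartment(1, None, 10.0, 1.0, "soma")  # second root
        with pytest.raises(ValueError, match="one root"):
            Morphology("custom", [c0, c1])
        with pytest.raises(ValueError, match="length and diameter"):
            Compartment(0, None, -5.0, 1.0, "soma")

    def test_serialization_round_trip(self, ca1_morph, tmp_path):
        path = tmp_path / "ca1.yaml"
        ca1_morph.save(path)
        back = Morphology.load(path)
        assert back.n == ca1_morph.n
        for a, b in zip(back.compartments, ca1_morph.compartments):
            assert a == b

    def test_table_export_rows_and_columns(self, ca3_morph):
        df = ca3_morph.to_frame()
        assert len(df) == 21
        assert {"parent", "role", "length_um", "diameter_um", "g_Na_ms_cm2"} <= set(df.columns)
        assert df.loc[0, "parent"] == -1


class TestRestingState:
    def test_rest_is_a_fixed_point(self, ca3_morph, ca3_rest):
        d = cable_rhs(ca3_morph, ca3_rest)
        assert np.max(np.abs(d.v)) < 1e-3  # mV/ms, within solver tolerance

    def test_rest_near_nominal_resting_potential(self, ca1_rest):
        assert np.all(ca1_rest.v > -70.0) and np.all(ca1_rest.v < -55.0)

    def test_gates_within_bounds(self, ca3_rest):
        for g, x in ca3_rest.gates.items():
            assert np.all(x >= 0.0) and np.all(x <= 1.0)


class TestPassiveCable:
    def test_two_compartment_steady_state_matches_resistive_network(self):
        """Step current into compartment 1 of a passive pair: steady-state
        deflections solve the analytic 2x2 conductance system."""
        m = passive_pair()
        g_leak = 0.1 * m.areas_cm2[0]            # mS per compartment
        g_c = m.axial_conductances_ms()[1]
        i_na = 0.1
        a = np.array([[g_leak + g_c, -g_c], [-g_c, g_leak + g_c]])
        expected = np.linalg.solve(a, np.array([i_na * 1e-3, 0.0]))  # mV deflection

        st = MembraneState.at_voltage(m, V_REST)
        inj = np.array([i_na, 0.0])

        def rhs(_t, y):
            return cable_rhs(m, MembraneState.unpack(y, 2), inj, None).pack()

        sol = solve_ivp(rhs, (0, 2000.0), st.pack(), method="BDF",
                        rtol=1e-10, atol=1e-12)
        v = MembraneState.unpack(sol.y[:, -1], 2).v
        assert np.allclose(v - V_REST, expected, rtol=1e-6)

    def test_passive_deflection_linear_in_current(self):
        m = passive_pair()

        def steady(i_na):
            inj = np.array([i_na, 0.0])
            rhs = lambda _t, y: cable_rhs(m, MembraneState.unpack(y, 2), inj, None).pack()
            sol = solve_ivp(rhs, (0, 2000.0),
                            MembraneState.at_voltage(m, V_REST).pack(),
                            method="BDF", rtol=1e-10, atol=1e-12)
            return MembraneState.unpack(sol.y[:, -1], 2).v - V_REST

        assert np.allclose(steady(0.2), 2.0 * steady(0.1), rtol=1e-6)

    def test_zero_input_rest_is_fixed_point(self):
        m = passive_pair()
        st = MembraneState.at_voltage(m, V_REST)
        d = cable_rhs(m, st)
        assert np.max(np.abs(d.v)) < 1e-9

    def test_dimension_mismatch_rejected(self, ca3_morph, ca3_rest):
        with pytest.raises(ValueError, match="per compartment"):
            cable_rhs(ca3_morph, ca3_rest, injected_na=np.zeros(3))


class TestTransmembraneCurrents:
    def test_no_injection_currents_sum_to_zero(self, ca3_burst_run, ca3_morph):
        """Kirchhoff conservation on an actual spiking trace: with the
        injected current added, per-cell membrane currents sum to it."""
        v = ca3_burst_run.cell_v("CA3")
        i_m = transmembrane_currents(ca3_morph, v)
        # without the source term the axial formulation sums to zero exactly
        assert np.max(np.abs(i_m.sum(axis=0))) < 1e-9

    def test_currents_sum_to_injected(self, ca3_burst_run, ca3_morph):
        inj = np.zeros(ca3_morph.n)
        inj[0] = 0.6
        i_m = transmembrane_currents(ca3_morph, ca3_burst_run.cell_v("CA3"), inj)
        assert np.allclose(i_m.sum(axis=0), 0.6, atol=1e-9)

    def test_single_compartment_current_equals_injection_at_steady_state(self):
        """One compartment: membrane current (outward positive) balances the
        injected current exactly once transients die out."""
        c = Compartment(0, None, 100.0, 10.0, "soma", channel_densities={"leak": 0.1})
        m = Morphology("custom", [c])
        inj = np.array([0.05])
        rhs = lambda _t, y: cable_rhs(m, MembraneState.unpack(y, 1), inj, None).pack()
        sol = solve_ivp(rhs, (0, 2000.0), MembraneState.at_voltage(m, V_REST).pack(),
                        method="BDF", rtol=1e-10, atol=1e-12)
        i_m = transmembrane_currents(m, sol.y[:1, -1:], inj)
        assert i_m[0, -1] == pytest.approx(0.05, rel=1e-9)


class TestSolverBehaviour:
    def test_resting_stability_zero_input(self):
        """1.5 s with no stimulus: every compartment stays within 0.5 mV."""
        cfg = gs.NetworkConfig(scenario="no_astro", n_ca1=0, duration_s=1.5,
                               stim_na=0.0)
        tr = gs.simulate(cfg)
        drift = np.abs(tr.v - tr.v[:, :1]).max()
        assert drift < 0.5

    def test_spike_time_convergence_under_step_refinement(self):
        """Halving dt moves the CA3 spike times by < 1 ms."""
        spikes = {}
        for dt in (0.025, 0.0125):
            cfg = gs.NetworkConfig(scenario="no_astro", n_ca1=0, duration_s=1.0,
                                   dt_ms=dt, record_dt_ms=0.1)
            spikes[dt] = gs.simulate(cfg).spike_times_ms("CA3")
        a, b = spikes[0.025], spikes[0.0125]
        n = min(a.size, b.size)
        assert n >= 1
        assert np.max(np.abs(a[:n] - b[:n])) < 1.0

    def test_engine_matches_reference_bdf_on_single_cell(self, ca3_morph, ca3_rest):
        """Cross-check: the production stepper against scipy BDF on the same
        right-hand side (300 ms of the driven CA3 cell)."""
        inj = np.zeros(ca3_morph.n)
        inj[0] = 0.6
        rhs = lambda _t, y: cable_rhs(ca3_morph,
                                      MembraneState.unpack(y, ca3_morph.n),
                                      inj, None).pack()
        sol = solve_ivp(rhs, (0, 300.0), ca3_rest.pack(), method="BDF",
                        rtol=1e-8, atol=1e-10, t_eval=np.arange(0, 300.0, 0.1))
        v_ref = sol.y[0]
        cfg = gs.NetworkConfig(scenario="no_astro", n_ca1=0, duration_s=0.3,
                               settle_s=0.0, record_dt_ms=0.1)
        v_eng = gs.simulate(cfg).detection_trace("CA3")
        t = np.arange(0, 300.0, 0.1)
        ref_spk = gs.detect_spikes(v_ref, t)
        eng_spk = gs.detect_spikes(v_eng[: t.size], t)
        assert ref_spk.size == eng_spk.size
        if ref_spk.size:
            assert np.max(np.abs(ref_spk - eng_spk)) < 2.0
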