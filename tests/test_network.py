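"""Network assembly, scenario semantics, integration and trace handling."""

import dataclasses

import numpy as np
import pytest

import gliosim as gs
from gliosim.astrocyte import AstrocyteParams
from gliosim.lfp import spike_synchrony
from gliosim.network import NetworkConfig, TraceSet, assemble, detect_spikes


class TestAssemble:
    def test_no_astro_has_no_astro_or_sic_states(self):
        asm = assemble(NetworkConfig(scenario="no_astro"))
        assert asm.sic_post.size == 0 and not asm.sic_cells

    def test_astro_on_delivers_sic_to_apical_spine_and_basal_dendrites(self):
        asm = assemble(NetworkConfig(scenario="astro_on"))
        assert asm.sic_cells == ["CA1_1", "CA1_2", "CA1_3", "CA1_4"]
        targets = {c: p - asm.cell_offsets[c] for c, p in
                   zip(asm.sic_cells, asm.sic_post)}
        assert targets["CA1_1"] == 22          # apical spine head
        assert all(targets[f"CA1_{i}"] == 3 for i in (2, 3, 4))  # basal shaft

    def test_ca1_4_projects_nowhere(self):
        asm = assemble(NetworkConfig(scenario="no_astro"))
        pre_cells = {s.pre_cell for s in asm.synapses}
        assert "CA1_4" not in pre_cells
        assert len(asm.synapses) == 4  # CA3->1 plus the 1->2->3->4 chain

    def test_multiplicities(self):
        asm = assemble(NetworkConfig(scenario="no_astro"))
        assert asm.synapses[0].multiplicity == 25
        assert all(s.multiplicity == 20 for s in asm.synapses[1:])

    def test_assembly_is_deterministic(self):
        a1 = assemble(NetworkConfig(scenario="astro_on"))
        a2 = assemble(NetworkConfig(scenario="astro_on"))
        assert np.array_equal(a1.v0, a2.v0)
        assert np.array_equal(a1.gdens, a2.gdens)

    def test_state_count_logged_near_paper_scale(self):
        asm = assemble(NetworkConfig(scenario="astro_on"))
        # 5 cells x (V + 8 gates + Ca pool) + synapse/SIC/astrocyte states
        assert 1100 <= asm.ode_count <= 1250


class TestScenarios:
    def test_unknown_scenario_names_valid_choices(self):
        with pytest.raises(ValueError, match="no_astro"):
            NetworkConfig(scenario="astro_off")

    def test_epileptiform_doubles_enmdar_conductance_only(self):
        base = NetworkConfig(scenario="astro_on")
        epi = NetworkConfig(scenario="epileptiform")
        assert epi.sic.conductance_scale == 2.0
        assert base.sic.conductance_scale == 1.0
        assert epi.astrocyte == base.astrocyte
        assert epi.ca3_synapse == base.ca3_synapse

    def test_clamp_control_pairs_clamp_with_doubled_conductance(self):
        cfg = NetworkConfig(scenario="ca_clamp_control")
        assert cfg.astrocyte.clamp_enabled
        assert cfg.astrocyte.clamp_value_nm == 100.0
        assert cfg.sic.conductance_scale == 2.0

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = NetworkConfig(scenario="epileptiform", duration_s=3.0)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert NetworkConfig.from_yaml(path) == cfg

    def test_overrides_dotted_keys_and_error_listing(self):
        cfg = NetworkConfig(scenario="astro_on")
        out = cfg.with_overrides({"sic.conductance_scale": 2.0, "duration_s": 5.0})
        assert out.sic.conductance_scale == 2.0 and out.duration_s == 5.0
        with pytest.raises(ValueError, match="sic.bogus"):
            cfg.with_overrides({"sic.bogus": 1})


class TestSimulate:
    def test_runs_are_bit_identical(self):
        cfg = NetworkConfig(scenario="astro_on", duration_s=1.5)
        v1 = gs.simulate(cfg).v
        v2 = gs.simulate(cfg).v
        assert np.array_equal(v1, v2)

    def test_zero_drive_is_silent(self):
        cfg = NetworkConfig(scenario="no_astro", duration_s=3.0, stim_na=0.0)
        tr = gs.simulate(cfg)
        assert all(tr.spike_times_ms(c).size == 0 for c in tr.cell_offsets)

    def test_response_latency_ordered_along_the_chain(self, no_astro_run):
        firsts = [no_astro_run.spike_times_ms(c)[0]
                  for c in ("CA3", "CA1_1", "CA1_2", "CA1_3", "CA1_4")]
        assert all(a < b for a, b in zip(firsts, firsts[1:]))

    def test_infinite_release_threshold_reproduces_no_astro_exactly(self):
        """Scenario nesting: with the release gate unreachable the astro_on
        CA1 voltages equal the astrocyte-free run to machine precision."""
        cfg0 = NetworkConfig(scenario="no_astro", duration_s=4.0)
        cfg1 = NetworkConfig(scenario="astro_on", duration_s=4.0,
                             astrocyte=AstrocyteParams(ca_release_threshold_nm=np.inf))
        tr0, tr1 = gs.simulate(cfg0), gs.simulate(cfg1)
        for c in ("CA1_1", "CA1_2", "CA1_3", "CA1_4"):
            assert np.array_equal(tr0.cell_v(c), tr1.cell_v(c))

    def test_astro_effects_start_only_after_first_threshold_crossing(self, astro_on_run,
                                                                     no_astro_run):
        events = astro_on_run.event_log()
        first_cross = events["ca_threshold_crossings_ms"][0]
        assert first_cross > 9000.0
        n = int(first_cross / astro_on_run.dt_ms) - 1
        for c in ("CA1_1", "CA1_4"):
            assert np.array_equal(astro_on_run.cell_v(c)[:, :n],
                                  no_astro_run.cell_v(c)[:, :n])

    def test_astrocyte_synchronises_ca1_firing(self, astro_on_run, no_astro_run):
        cells = ["CA1_2", "CA1_3", "CA1_4"]
        assert spike_synchrony(astro_on_run, cells) > \
            spike_synchrony(no_astro_run, cells)

    def test_two_sic_events_per_suprathreshold_epoch(self, astro_on_run):
        events = astro_on_run.event_log()
        ca = astro_on_run.astro["ca_um"].to_numpy() * 1e3
        thr = astro_on_run.config.astrocyte.ca_release_threshold_nm
        n_epochs = int(np.sum((ca[1:] > thr) & (ca[:-1] <= thr)))
        assert n_epochs >= 1
        assert len(events["sic_onsets_ms"]) == 2 * n_epochs

    def test_diverging_run_names_worst_compartment(self):
        cfg = NetworkConfig(scenario="no_astro", n_ca1=0, duration_s=0.2,
                            stim_na=1e9)  # absurd drive forces blow-up
        with pytest.raises(RuntimeError, match="compartment"):
            gs.simulate(cfg)


class TestTraceSet:
    def test_save_load_round_trip(self, tmp_path):
        tr = gs.simulate(NetworkConfig(scenario="astro_on", duration_s=1.0))
        path = tmp_path / "run.npz"
        tr.save(path)
        back = TraceSet.load(path)
        assert np.array_equal(back.v, tr.v)
        assert np.array_equal(back.t_ms, tr.t_ms)
        assert back.config == tr.config
        assert np.allclose(back.astro.to_numpy(), tr.astro.to_numpy())

    def test_csv_export(self, tmp_path):
        import pandas as pd
        tr = gs.simulate(NetworkConfig(scenario="no_astro", duration_s=0.5))
        path = tmp_path / "v.csv"
        tr.export_csv(path)
        df = pd.read_csv(path)
        assert "v_CA3_mv" in df.columns and len(df) == tr.t_ms.size

    def test_spike_detection_threshold_and_refractory(self):
        t = np.arange(0, 100.0, 0.5)
        v = np.full(t.size, -60.0)
        for t0 in (10.0, 11.0, 40.0):  # second crossing inside refractory
            v[(t >= t0) & (t < t0 + 0.5)] = 10.0
        st = detect_spikes(v, t, threshold_mv=0.0, refractory_ms=2.0)
        assert np.allclose(st, [10.0, 40.0])
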