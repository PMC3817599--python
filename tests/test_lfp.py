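"""Field potential kernels, PSD summaries and burst segmentation."""

import numpy as np
import pytest

from gliosim import lfp as L


def point_geometry(positions, rho=643.0, electrode=(0.0, 0.0, 0.0)):
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    return L.ElectrodeGeometry(
        centers_um=pos, starts_um=pos.copy(), ends_um=pos.copy(),
        rho_ohm_cm=np.full(len(pos), rho), include=np.ones(len(pos), dtype=bool),
        electrode_um=np.asarray(electrode, dtype=float))


class TestFieldPotential:
    def test_single_point_source_printed_value(self):
        """1 nA at 25 um in 643 Ohm*cm -> ~20.5 uV."""
        geo = point_geometry([[25.0, 0.0, 0.0]])
        cfg = L.LFPConfig(source_model="point_source")
        phi = L.field_potential(np.array([[1.0]]), geo, cfg)
        assert phi[0] == pytest.approx(20.5e-6, rel=2e-3)
        assert phi[0] == pytest.approx(6.43 * 1e-9 / (4 * np.pi * 25e-6), rel=1e-12)

    def test_zero_currents_zero_field(self):
        geo = point_geometry([[25.0, 0.0, 0.0], [50.0, 0.0, 0.0]])
        cfg = L.LFPConfig(source_model="point_source")
        phi = L.field_potential(np.zeros((2, 10)), geo, cfg)
        assert np.all(phi == 0.0)

    def test_opposite_equidistant_sources_cancel(self):
        geo = point_geometry([[0.0, 25.0, 0.0], [0.0, -25.0, 0.0]])
        cfg = L.LFPConfig(source_model="point_source")
        phi = L.field_potential(np.array([[1.0], [-1.0]]), geo, cfg)
        assert phi[0] == pytest.approx(0.0, abs=1e-18)

    def test_superposition(self):
        geo = point_geometry([[25.0, 0.0, 0.0], [40.0, 10.0, 0.0]])
        cfg = L.LFPConfig(source_model="point_source")
        i1 = np.array([[1.0, 0.5], [0.0, 0.0]])
        i2 = np.array([[0.0, 0.0], [-0.3, 0.8]])
        phi = L.field_potential(i1 + i2, geo, cfg)
        assert np.allclose(phi, L.field_potential(i1, geo, cfg)
                           + L.field_potential(i2, geo, cfg), rtol=1e-12)

    def test_inverse_distance_scaling(self):
        cfg = L.LFPConfig(source_model="point_source")
        near = L.field_potential(np.array([[1.0]]),
                                 point_geometry([[12.5, 0.0, 0.0]]), cfg)
        far = L.field_potential(np.array([[1.0]]),
                                point_geometry([[25.0, 0.0, 0.0]]), cfg)
        assert near[0] == pytest.approx(2.0 * far[0], rel=1e-12)

    def test_line_source_degrades_to_point_for_short_segment(self):
        pos = np.array([[25.0, 0.0, 0.0]])
        geo_line = L.ElectrodeGeometry(
            centers_um=pos, starts_um=pos - [0.0, 0.05, 0.0],
            ends_um=pos + [0.0, 0.05, 0.0], rho_ohm_cm=np.array([643.0]),
            include=np.ones(1, dtype=bool), electrode_um=np.zeros(3))
        phi_line = L.field_potential(np.array([[1.0]]), geo_line,
                                     L.LFPConfig(source_model="line_source"))
        phi_point = L.field_potential(np.array([[1.0]]), point_geometry([[25.0, 0, 0]]),
                                      L.LFPConfig(source_model="point_source"))
        assert phi_line[0] == pytest.approx(phi_point[0], rel=1e-5)

    def test_is_axon_always_excluded(self):
        with pytest.raises(ValueError):
            L.LFPConfig(excluded_roles=("axon",))

    def test_geometry_rejects_electrode_on_source(self):
        geo = point_geometry([[0.0, 0.0, 0.0]])
        with pytest.raises(ValueError):
            geo.distances_um()


class TestDefaultGeometry:
    def test_electrode_25um_beyond_fourth_soma(self, ca1_morph):
        geo = L.build_geometry(ca1_morph, n_cells=4)
        assert np.allclose(geo.electrode_um, [100.0, 0.0, 0.0])
        soma_rows = [k * ca1_morph.n for k in range(4)]
        x = geo.centers_um[soma_rows, 0]
        assert np.allclose(x, [0.0, 25.0, 50.0, 75.0])

    def test_is_and_axon_rows_masked(self, ca1_morph):
        geo = L.build_geometry(ca1_morph, n_cells=4)
        for k in range(4):
            for local, c in enumerate(ca1_morph.compartments):
                included = geo.include[k * ca1_morph.n + local]
                assert included == (c.role_tag not in ("IS", "axon"))

    def test_regional_resistivities(self, ca1_morph):
        geo = L.build_geometry(ca1_morph, n_cells=1)
        rho = geo.rho_ohm_cm
        roles = [c.role_tag for c in ca1_morph.compartments]
        assert rho[roles.index("soma")] == 643.0
        basal = [i for i, r in enumerate(roles) if r == "basal_dendrite"]
        assert np.all(rho[basal] == 260.0)
        apical = [i for i, r in enumerate(roles) if r == "apical_dendrite"]
        assert rho[apical[0]] == 643.0      # proximal apical
        assert rho[apical[-1]] == 287.0     # distal apical


class TestPSD:
    fs = 1000.0

    def test_pure_tone_peak(self):
        t = np.arange(0, 50.0, 1.0 / self.fs)
        spec = L.psd(np.sin(2 * np.pi * 2.0 * t), self.fs)
        assert spec.peak_frequency_hz == pytest.approx(2.0, abs=0.05)

    def test_tone_mix_dominant_and_secondary(self):
        t = np.arange(0, 50.0, 1.0 / self.fs)
        x = 4.0 * np.sin(2 * np.pi * 2.0 * t) + np.sin(2 * np.pi * 8.0 * t)
        spec = L.psd(x, self.fs)
        assert spec.peak_frequency_hz == pytest.approx(2.0, abs=0.05)
        i8 = np.argmin(np.abs(spec.freq_hz - 8.0))
        assert spec.power[i8] > 100 * np.median(spec.power[spec.freq_hz > 0.25])

    def test_white_noise_has_no_dominant_band(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(int(50 * self.fs))
        edges = np.linspace(1.0, 100.0, 11)
        bands = {f"b{i}": (edges[i], edges[i + 1]) for i in range(10)}
        spec = L.psd(x, self.fs, analysis_band=(1.0, 100.0), bands=bands)
        powers = np.array(list(spec.band_powers.values()))
        assert powers.max() < 3.0 * np.median(powers)

    def test_parseval_consistency(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(4096)
        spec = L.psd(x, self.fs)
        df = spec.freq_hz[1] - spec.freq_hz[0]
        assert spec.power.sum() * df == pytest.approx(np.var(x), rel=1e-6)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            L.psd(np.array([1.0]), self.fs)
        with pytest.raises(ValueError):
            L.psd(np.zeros(100), self.fs, nperseg=1024)


class TestBurstMetrics:
    def test_constructed_100hz_train(self):
        """Groups of 10 spikes at 10 ms spacing every 1.5 s: intraburst
        100 Hz, repetition ~0.667 Hz."""
        t = np.concatenate([k * 1500.0 + np.arange(10) * 10.0 for k in range(5)])
        bm = L.burst_metrics(t, gap_ms=100.0)
        assert bm.n_bursts == 5
        assert bm.intraburst_hz == pytest.approx(100.0, rel=1e-9)
        assert bm.repetition_hz == pytest.approx(1.0 / 1.5, rel=1e-9)
        assert all(d == pytest.approx(90.0) for d in bm.durations_ms)

    def test_single_burst_repetition_flagged_undefined(self):
        bm = L.burst_metrics(np.arange(10) * 10.0)
        assert bm.repetition_hz is None
        assert bm.intraburst_hz == pytest.approx(100.0)
        assert any("repetition" in f for f in bm.flags)

    def test_single_event_flagged(self):
        bm = L.burst_metrics([5.0])
        assert np.isnan(bm.intraburst_hz) and bm.repetition_hz is None
        assert bm.flags

    def test_uniform_train_with_wide_gap_is_one_burst(self):
        """A uniform 5 Hz train segments into a single full-length burst
        when the gap threshold exceeds the 200 ms inter-spike interval."""
        t = np.arange(0.0, 4000.0, 200.0)
        bm = L.burst_metrics(t, gap_ms=300.0)
        assert bm.n_bursts == 1
        assert bm.intraburst_hz == pytest.approx(5.0)
        assert bm.durations_ms[0] == pytest.approx(t[-1] - t[0])

    def test_uniform_train_below_gap_splits_every_event(self):
        t = np.arange(0.0, 2000.0, 200.0)
        bm = L.burst_metrics(t, gap_ms=100.0)
        assert bm.n_bursts == t.size

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            L.burst_metrics([])


class TestEpisodes:
    def test_episode_segmentation_on_gated_oscillation(self):
        fs = 1000.0
        t = np.arange(0, 6.0, 1.0 / fs)
        gate = ((t > 1.0) & (t < 1.6)) | ((t > 3.5) & (t < 4.1))
        x = np.sin(2 * np.pi * 60.0 * t) * gate
        eps = L.lfp_episodes(x, fs)
        assert len(eps) == 2
        for (a, b), (lo, hi) in zip(eps, [(1000.0, 1600.0), (3500.0, 4100.0)]):
            assert a == pytest.approx(lo, abs=60.0)
            assert b == pytest.approx(hi, abs=60.0)
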