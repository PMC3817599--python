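"""Scenario runner, run manifests and deterministic test fixtures."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .lfp import (LFPConfig, build_geometry, burst_metrics, compute_lfp,
                  lfp_episodes, psd)
from .morphology import build_morphology
from .network import SCENARIOS, NetworkConfig, simulate

__all__ = ["RunManifest", "run_scenario", "make_fixture", "FIXTURE_KINDS"]


@dataclass
class RunManifest:
    scenario: str
    config: dict
    version: str
    ode_count: int
    solver_stats: dict
    wall_s: float
    outputs: dict = field(default_factory=dict)   # filename -> sha256

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=float)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_scenario(name: str, outdir, overrides: dict | None = None,
                 duration_s: float | None = None,
                 analysis_skip_s: float = 0.0) -> RunManifest:
    """Execute assemble -> simulate -> LFP -> PSD -> metrics and persist all.

    ``overrides`` uses dotted config keys (e.g. ``"sic.conductance_scale"``);
    unknown scenario names or override keys raise configuration errors.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; valid choices: {', '.join(SCENARIOS)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = NetworkConfig(scenario=name)
    if duration_s is not None:
        config = config.with_overrides({"duration_s": duration_s})
    if overrides:
        config = config.with_overrides(overrides)

    t0 = time.perf_counter()
    traces = simulate(config)
    ca1 = build_morphology("CA1")
    lfp = compute_lfp(traces, ca1)
    fs = traces.fs_hz
    skip = int(round(analysis_skip_s * fs))
    spec = psd(lfp[skip:], fs)

    metrics = {"scenario": name, "ode_count": traces.ode_count,
               "peak_frequency_hz": spec.peak_frequency_hz,
               "delta_fraction": spec.delta_fraction,
               "band_powers_v2": spec.band_powers,
               "spikes": {}, "bursts": {}}
    for cell in traces.cell_offsets:
        st = traces.spike_times_ms(cell)
        metrics["spikes"][cell] = len(st)
        if st.size:
            bm = burst_metrics(st)
            metrics["bursts"][cell] = {
                "n_bursts": bm.n_bursts, "intraburst_hz": bm.intraburst_hz,
                "repetition_hz": bm.repetition_hz, "flags": bm.flags}
    episodes = lfp_episodes(lfp[skip:], fs)
    metrics["lfp_episodes_ms"] = [[a, b] for a, b in episodes]
    if traces.astro is not None:
        metrics["astro_release_events"] = int(traces.astro["release_count"].iloc[-1])
    metrics["events"] = traces.event_log()
    wall = time.perf_counter() - t0

    traces.save(outdir / "traces.npz")
    traces.export_csv(outdir / "traces.csv")
    pd.DataFrame({"t_ms": traces.t_ms[skip:], "lfp_v": lfp[skip:]}).to_csv(
        outdir / "lfp.csv", index=False)
    pd.DataFrame({"freq_hz": spec.freq_hz, "psd_v2_hz": spec.power}).to_csv(
        outdir / "psd.csv", index=False)
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, default=float)

    manifest = RunManifest(scenario=name, config=traces.config.to_dict(),
                           version=__version__, ode_count=traces.ode_count,
                           solver_stats=traces.solver_stats, wall_s=round(wall, 3))
    for f in ("traces.npz", "traces.csv", "lfp.csv", "psd.csv", "metrics.json"):
        manifest.outputs[f] = _sha256(outdir / f)
    manifest.save(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Deterministic fixtures used by the unit tests and docs.
# ---------------------------------------------------------------------------

FIXTURE_KINDS = ("passive_cable", "spike_train", "tone_mix", "current_dipole")


def make_fixture(kind: str, outdir):
    """Write one of the small deterministic fixtures; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "passive_cable":
        # two passive compartments, step current into the first; the analytic
        # steady state solves the 2x2 resistive network
        g1 = g2 = 1e-5   # mS (leak conductance per compartment)
        gc = 2e-5        # mS (axial coupling)
        i_na = 0.1       # nA into compartment 1
        i_ua = i_na * 1e-3
        a = np.array([[g1 + gc, -gc], [-gc, g2 + gc]])
        v = np.linalg.solve(a, np.array([i_ua, 0.0]))  # deflection from rest, mV
        spec = {"g_leak_ms": [g1, g2], "g_coupling_ms": gc, "injected_na": i_na,
                "v_rest_mv": -60.0,
                "steady_deflection_mv": [float(v[0]), float(v[1])]}
        path = outdir / "passive_cable.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(spec, fh, sort_keys=False)
        return [path]
    if kind == "spike_train":
        # groups of 10 spikes at 10 ms spacing, onsets every 1.5 s:
        # intraburst 100 Hz, repetition ~0.667 Hz
        t = np.concatenate([k * 1500.0 + np.arange(10) * 10.0 for k in range(6)])
        path = outdir / "spike_train.csv"
        pd.DataFrame({"t_ms": t}).to_csv(path, index=False)
        return [path]
    if kind == "tone_mix":
        fs = 1000.0
        t = np.arange(0, 50.0, 1.0 / fs)
        x = 4.0 * np.sin(2 * np.pi * 2.0 * t) + 1.0 * np.sin(2 * np.pi * 8.0 * t)
        path = outdir / "tone_mix.csv"
        pd.DataFrame({"t_s": t, "x": x}).to_csv(path, index=False)
        return [path]
    if kind == "current_dipole":
        # two equal and opposite point sources equidistant from the electrode
        df = pd.DataFrame({
            "x_um": [0.0, 0.0], "y_um": [25.0, -25.0], "z_um": [0.0, 0.0],
            "i_na": [1.0, -1.0], "rho_ohm_cm": [643.0, 643.0]})
        path = outdir / "current_dipole.csv"
        df.to_csv(path, index=False)
        return [path]
    raise ValueError(f"unknown fixture kind {kind!r}; valid: {', '.join(FIXTURE_KINDS)}")
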