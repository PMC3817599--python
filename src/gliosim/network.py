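"""Network assembly and simulation: 1 CA3 + 4 CA1 neurons + astrocyte.

The wiring follows the tripartite-synapse circuit: the CA3 neuron makes 25
pooled Schaffer-collateral contacts onto the apical spine of CA1 neuron 1
(stratum radiatum); the CA1 neurons chain 1->2, 2->3, 3->4 through 20
pooled contacts each onto the basal spine of the next cell (stratum
oriens); CA1 neuron 4 projects nowhere.  The astrocyte senses cleft
glutamate at the CA3 -> CA1-1 synapse and, when its Ca2+ release gate
opens, drives slow inward currents through extrasynaptic NR2B receptors on
the apical spine of CA1 1 and the basal dendrites of CA1 2-4.

Scenarios
---------
``no_astro``          network without astrocyte states or SIC gates
``astro_on``          full tripartite network
``epileptiform``      astro_on with the eNMDAR conductance doubled
``ca_clamp_control``  astrocytic Ca2+ clamped at 100 nM (gliotransmission
                      incapacitated) with the conductance still doubled

The integrator is a fixed-step backward-difference (backward-Euler) solve
of the coupled system (see ``gliosim._engine``); runs are deterministic.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import _engine
from .astrocyte import AstrocyteParams, basal_state
from .channels import (CHANNELS, E_NA, E_CA, E_K, E_LEAK, CHI_SAT,
                       Q_ALPHA_SCALE, Q_ALPHA_MAX, Q_BETA)
from .morphology import Morphology, build_morphology, resting_state, transmembrane_currents
from .synapses import (FastSynapseParams, GlutamateReleaseParams, SICParams,
                       SynapseSpec)

logger = logging.getLogger("gliosim")

SCENARIOS = ("no_astro", "astro_on", "epileptiform", "ca_clamp_control")

CELL_NAMES = ("CA3", "CA1_1", "CA1_2", "CA1_3", "CA1_4")

#: resting states are expensive (stiff settle + Newton polish); cache them
#: per morphology content within a process
_REST_CACHE: dict = {}

#: compartment indices within the canonical morphologies
CA3_SOMA_COMP = 0
CA1_AXON_COMP = 20
CA1_BASAL_SPINE_COMP = 21
CA1_APICAL_SPINE_COMP = 22
CA1_BASAL_SIC_COMP = 3   # basal shaft at the original 6th compartment


@dataclass
class NetworkConfig:
    scenario: str = "no_astro"
    duration_s: float = 20.0
    settle_s: float = 0.5
    stim_na: float = 0.6                  # constant somatic current into CA3
    dt_ms: float = 0.025
    record_dt_ms: float = 0.5
    n_ca1: int = 4
    ca3_ca1_multiplicity: int = 25
    ca1_ca1_multiplicity: int = 20
    #: pooled extrasynaptic NR2B sites per SIC delivery target (fewer than
    #: the synaptic contact count: eNMDARs sit perisynaptically at a subset
    #: of contacts reached by astrocytic glutamate)
    enmdar_sites: int = 3
    spike_threshold_mv: float = 0.0       # absolute, upward crossing in the axon
    spike_refractory_ms: float = 2.0
    glutamate: GlutamateReleaseParams = field(default_factory=GlutamateReleaseParams)
    # pooled Schaffer input sets the lead cell's rate; the chain conductance
    # sits at unity gain so activity neither dies out nor runs away
    ca3_synapse: FastSynapseParams = field(
        default_factory=lambda: FastSynapseParams(g_ampa_ns=1.0, g_nmda_ns=0.6))
    ca1_synapse: FastSynapseParams = field(
        default_factory=lambda: FastSynapseParams(g_ampa_ns=0.8, g_nmda_ns=0.28))
    sic: SICParams = field(default_factory=SICParams)
    astrocyte: AstrocyteParams = field(default_factory=AstrocyteParams)

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; valid choices: {', '.join(SCENARIOS)}")
        if self.scenario in ("epileptiform", "ca_clamp_control"):
            self.sic = dataclasses.replace(self.sic, conductance_scale=2.0)
        if self.scenario == "ca_clamp_control":
            self.astrocyte = dataclasses.replace(self.astrocyte, clamp_enabled=True,
                                                 clamp_value_nm=100.0)

    @property
    def has_astro(self) -> bool:
        return self.scenario != "no_astro"

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        for key, sub in (("glutamate", GlutamateReleaseParams),
                         ("ca3_synapse", FastSynapseParams),
                         ("ca1_synapse", FastSynapseParams),
                         ("sic", SICParams), ("astrocyte", AstrocyteParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_overrides(self, overrides: dict) -> "NetworkConfig":
        d = self.to_dict()
        bad = []
        for key, val in overrides.items():
            parts = key.split(".")
            node = d
            for p in parts[:-1]:
                if not isinstance(node, dict) or p not in node:
                    bad.append(key)
                    break
                node = node[p]
            else:
                if parts[-1] not in node:
                    bad.append(key)
                else:
                    node[parts[-1]] = val
        if bad:
            raise ValueError(f"invalid override keys: {sorted(bad)}")
        return NetworkConfig.from_dict(d)


@dataclass
class Assembly:
    """Flattened coupled system: arrays for the engine plus bookkeeping."""

    config: NetworkConfig
    morphologies: dict                 # cell name -> Morphology
    cell_offsets: dict                 # cell name -> first global comp index
    n_comp: int
    parent: np.ndarray
    gax: np.ndarray
    gax_sum: np.ndarray
    cap: np.ndarray
    area: np.ndarray
    gdens: np.ndarray                  # (n, 7) densities * area, mS
    pool_phi: np.ndarray
    pool_tau_ms: np.ndarray
    inj_ua: np.ndarray
    synapses: list                     # SynapseSpec, global comp indices resolved
    syn_pre: np.ndarray
    syn_post: np.ndarray
    syn_gampa: np.ndarray
    syn_gnmda: np.ndarray
    sic_post: np.ndarray
    sic_g: np.ndarray
    sic_cells: list
    v0: np.ndarray
    gates0: np.ndarray
    chi0: np.ndarray
    ode_count: int

    def global_comp(self, cell: str, comp: int) -> int:
        return self.cell_offsets[cell] + comp


@dataclass
class TraceSet:
    """Recorded traces on a uniform grid (time in ms from stimulus onset)."""

    t_ms: np.ndarray
    v: np.ndarray                      # (n_comp, n_t), absolute mV
    comp_table: pd.DataFrame           # cell, local index, role, rows align with v
    cell_offsets: dict
    glu_mm: np.ndarray                 # (n_syn, n_t) cleft glutamate per connection
    h: np.ndarray                      # (n_sic, n_t) SIC gate per target
    sic_cells: list
    astro: pd.DataFrame | None         # ca_um, ip3_um, w, vesicle, sigma, release_count
    config: NetworkConfig
    ode_count: int
    solver_stats: dict = field(default_factory=dict)

    @property
    def dt_ms(self) -> float:
        return float(self.t_ms[1] - self.t_ms[0])

    @property
    def fs_hz(self) -> float:
        return 1e3 / self.dt_ms

    def cell_slice(self, cell: str) -> slice:
        start = self.cell_offsets[cell]
        n = 21 if cell == "CA3" else 23
        return slice(start, start + n)

    def cell_v(self, cell: str) -> np.ndarray:
        return self.v[self.cell_slice(cell)]

    def detection_trace(self, cell: str) -> np.ndarray:
        """Voltage of the spike-detection compartment (axon; CA3 has no
        explicit axon, its soma carries the burst signature)."""
        comp = CA3_SOMA_COMP if cell == "CA3" else CA1_AXON_COMP
        return self.v[self.cell_offsets[cell] + comp]

    def spike_times_ms(self, cell: str) -> np.ndarray:
        cfg = self.config
        return detect_spikes(self.detection_trace(cell), self.t_ms,
                             cfg.spike_threshold_mv, cfg.spike_refractory_ms)

    def event_log(self) -> dict:
        out = {c: self.spike_times_ms(c).tolist() for c in self.cell_offsets}
        if self.astro is not None:
            ca_nm = self.astro["ca_um"].to_numpy() * 1e3
            thr = self.config.astrocyte.ca_release_threshold_nm
            up = np.flatnonzero((ca_nm[1:] > thr) & (ca_nm[:-1] <= thr))
            out["ca_threshold_crossings_ms"] = self.t_ms[1:][up].tolist()
            sig = self.astro["sigma"].to_numpy()
            on = np.flatnonzero((sig[1:] > 0) & (sig[:-1] == 0))
            out["sic_onsets_ms"] = self.t_ms[1:][on].tolist()
        return out

    def transmembrane_currents_na(self, cell: str, morph: Morphology,
                                  injected_na: np.ndarray | None = None) -> np.ndarray:
        return transmembrane_currents(morph, self.cell_v(cell), injected_na)

    # -- persistence --------------------------------------------------------

    def save(self, path):
        astro = self.astro.to_numpy() if self.astro is not None else np.empty((0, 6))
        np.savez_compressed(
            path, t_ms=self.t_ms, v=self.v, glu_mm=self.glu_mm, h=self.h,
            astro=astro, has_astro=self.astro is not None,
            sic_cells=np.array(self.sic_cells, dtype=object),
            comp_cell=self.comp_table["cell"].to_numpy(dtype=object),
            comp_local=self.comp_table["local"].to_numpy(),
            comp_role=self.comp_table["role"].to_numpy(dtype=object),
            config_yaml=yaml.safe_dump(self.config.to_dict()),
            ode_count=self.ode_count,
            solver_stats=yaml.safe_dump(self.solver_stats),
        )

    @classmethod
    def load(cls, path) -> "TraceSet":
        z = np.load(path, allow_pickle=True)
        config = NetworkConfig.from_dict(yaml.safe_load(str(z["config_yaml"])))
        comp_table = pd.DataFrame({
            "cell": z["comp_cell"], "local": z["comp_local"], "role": z["comp_role"]})
        offsets = {}
        for i, c in enumerate(comp_table["cell"]):
            offsets.setdefault(str(c), i)
        astro = None
        if bool(z["has_astro"]):
            astro = pd.DataFrame(z["astro"], columns=[
                "ca_um", "ip3_um", "w", "vesicle", "sigma", "release_count"])
        return cls(t_ms=z["t_ms"], v=z["v"], comp_table=comp_table,
                   cell_offsets=offsets, glu_mm=z["glu_mm"], h=z["h"],
                   sic_cells=[str(s) for s in z["sic_cells"]], astro=astro,
                   config=config, ode_count=int(z["ode_count"]),
                   solver_stats=yaml.safe_load(str(z["solver_stats"])) or {})

    def export_csv(self, path):
        """Delimited-text export of the detection-compartment voltages."""
        cols = {"t_ms": self.t_ms}
        for c in self.cell_offsets:
            cols[f"v_{c}_mv"] = self.detection_trace(c)
        pd.DataFrame(cols).to_csv(path, index=False)


def detect_spikes(v_mv: np.ndarray, t_ms: np.ndarray, threshold_mv: float = 0.0,
                  refractory_ms: float = 2.0) -> np.ndarray:
    """Spike times (ms) from upward threshold crossings with a refractory gap."""
    v = np.asarray(v_mv, dtype=float)
    above = v >= threshold_mv
    idx = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if idx.size == 0:
        return np.empty(0)
    times = np.asarray(t_ms, dtype=float)[idx]
    keep = [times[0]]
    for t in times[1:]:
        if t - keep[-1] >= refractory_ms:
            keep.append(t)
    return np.array(keep)


# ---------------------------------------------------------------------------


def _wire(config: NetworkConfig) -> list:
    """The SynapseSpec list of the Figure-1 circuit."""
    if config.n_ca1 == 0:  # isolated CA3 / CA3+astrocyte subsystem
        return []
    syns = [SynapseSpec("CA3", CA3_SOMA_COMP, "CA1_1", CA1_APICAL_SPINE_COMP,
                        multiplicity=config.ca3_ca1_multiplicity, receptors="fast",
                        fast_params=config.ca3_synapse)]
    for i in range(1, config.n_ca1):  # chain 1->2, 2->3, 3->4; CA1_4 projects nowhere
        syns.append(SynapseSpec(f"CA1_{i}", CA1_AXON_COMP, f"CA1_{i + 1}",
                                CA1_BASAL_SPINE_COMP,
                                multiplicity=config.ca1_ca1_multiplicity,
                                receptors="fast", fast_params=config.ca1_synapse))
    return syns


def assemble(config: NetworkConfig) -> Assembly:
    """Flatten the configured network into one coupled ODE system."""
    ca3 = build_morphology("CA3")
    ca1 = build_morphology("CA1")
    morphs = {"CA3": ca3}
    for i in range(1, config.n_ca1 + 1):
        morphs[f"CA1_{i}"] = ca1

    offsets, off = {}, 0
    for name, m in morphs.items():
        offsets[name] = off
        off += m.n
    n = off

    parent = np.full(n, -1, dtype=np.int64)
    gax = np.zeros(n)
    cap = np.zeros(n)
    area = np.zeros(n)
    gdens = np.zeros((n, len(_engine.CHANNEL_ORDER)))
    pool_phi = np.zeros(n)
    pool_tau = np.zeros(n)
    chan_index = {c: j for j, c in enumerate(_engine.CHANNEL_ORDER)}
    rest_cache = _REST_CACHE
    v0 = np.zeros(n)
    gates0 = np.zeros((n, len(_engine.GATE_ORDER)))
    chi0 = np.zeros(n)

    for name, m in morphs.items():
        o = offsets[name]
        g = m.axial_conductances_ms()
        key = hash(yaml.safe_dump(m.to_dict()))
        if key not in rest_cache:
            rest_cache[key] = resting_state(m)
        rest = rest_cache[key]
        for i, c in enumerate(m.compartments):
            gi = o + i
            parent[gi] = -1 if c.parent is None else o + c.parent
            gax[gi] = g[i]
            cap[gi] = c.membrane_capacitance_uf_cm2 * c.area_cm2
            area[gi] = c.area_cm2
            for cname, dens in c.channel_densities.items():
                gdens[gi, chan_index[cname]] = dens * c.area_cm2
            pool_phi[gi] = c.ca_pool_phi
            pool_tau[gi] = c.ca_pool_tau_ms
        v0[o:o + m.n] = rest.v
        for j, gname in enumerate(_engine.GATE_ORDER):
            gates0[o:o + m.n, j] = rest.gates[gname]
        chi0[o:o + m.n] = rest.chi

    gax_sum = gax.copy()
    for i in range(n):
        if parent[i] >= 0:
            gax_sum[parent[i]] += gax[i]

    inj_ua = np.zeros(n)
    inj_ua[offsets["CA3"] + CA3_SOMA_COMP] = config.stim_na * 1e-3

    syns = _wire(config)
    syn_pre = np.array([offsets[s.pre_cell] + s.pre_comp for s in syns], dtype=np.int64)
    syn_post = np.array([offsets[s.post_cell] + s.post_comp for s in syns], dtype=np.int64)
    syn_gampa = np.array([s.multiplicity * s.fast_params.g_ampa_ns * 1e-6 for s in syns])
    syn_gnmda = np.array([s.multiplicity * s.fast_params.g_nmda_ns * 1e-6 for s in syns])
    n_real_syns = len(syns)
    if not syns and config.has_astro:
        # sensing-only entry: the astrocyte reads the CA3 release-site cleft
        # glutamate (Eq.-1 transform of the CA3 voltage) with no postsynaptic
        # conductance attached
        syn_pre = np.array([offsets["CA3"] + CA3_SOMA_COMP], dtype=np.int64)
        syn_post = syn_pre.copy()
        syn_gampa = np.zeros(1)
        syn_gnmda = np.zeros(1)

    if config.has_astro:
        sic_cells = [f"CA1_{i}" for i in range(1, config.n_ca1 + 1)]
        sic_post, sic_g = [], []
        for cell in sic_cells:
            comp = CA1_APICAL_SPINE_COMP if cell == "CA1_1" else CA1_BASAL_SIC_COMP
            sic_post.append(offsets[cell] + comp)
            sic_g.append(config.sic.conductance_scale * config.sic.g_nr2b_ns
                         * config.enmdar_sites * 1e-6)
        sic_post = np.array(sic_post, dtype=np.int64)
        sic_g = np.array(sic_g)
    else:
        sic_cells = []
        sic_post = np.empty(0, dtype=np.int64)
        sic_g = np.empty(0)

    n_gates = len(_engine.GATE_ORDER)
    ode_count = n * (2 + n_gates) + 2 * n_real_syns
    if config.has_astro:
        ode_count += len(sic_post) + 4  # h gates + (Ca, IP3, w, vesicle pool)
    logger.info("assembled %d compartments, %d state variables (paper reports 1247; "
                "delta %+d)", n, ode_count, ode_count - 1247)

    return Assembly(config=config, morphologies=morphs, cell_offsets=offsets,
                    n_comp=n, parent=parent, gax=gax, gax_sum=gax_sum, cap=cap,
                    area=area, gdens=gdens, pool_phi=pool_phi,
                    pool_tau_ms=pool_tau, inj_ua=inj_ua, synapses=syns,
                    syn_pre=syn_pre, syn_post=syn_post, syn_gampa=syn_gampa,
                    syn_gnmda=syn_gnmda, sic_post=sic_post, sic_g=sic_g,
                    sic_cells=sic_cells, v0=v0, gates0=gates0, chi0=chi0,
                    ode_count=ode_count)


def simulate(config: NetworkConfig | None = None, assembly: Assembly | None = None,
             **overrides) -> TraceSet:
    """Integrate the assembled network and return the recorded traces.

    A settle interval (``config.settle_s``, no stimulus) precedes the
    recorded window; time zero of the returned grid is stimulus onset.
    """
    if assembly is None:
        if config is None:
            config = NetworkConfig(**overrides)
        elif overrides:
            config = dataclasses.replace(config, **overrides)
        assembly = assemble(config)
    config = assembly.config

    dt = config.dt_ms
    stride = max(1, int(round(config.record_dt_ms / dt)))
    n_steps = int(round(config.duration_s * 1e3 / dt))
    n_settle = int(round(config.settle_s * 1e3 / dt))
    nrec = (n_steps + stride - 1) // stride

    vmin, dvinv, xinf_tab, dec_tab = _engine.build_gate_tables(dt)

    glu = config.glutamate
    nsyn = assembly.syn_pre.size
    glu_gmax = np.full(nsyn, glu.g_max_mm)
    glu_vhalf = np.full(nsyn, glu.v_rest_mv + glu.v_p_mv)  # absolute half-max voltage
    glu_kp = np.full(nsyn, glu.k_p_mv)
    fp = config.ca3_synapse

    sic = config.sic
    sic_dec = np.exp(-dt / sic.tau_2_ms)
    sic_gain = (sic.tau_2_ms / sic.tau_1_ms) * (1.0 - sic_dec)

    ap_obj = config.astrocyte
    ap = np.array([ap_obj.v1_per_s, ap_obj.v2_per_s, ap_obj.v3_um_per_s, ap_obj.k3_um,
                   ap_obj.d1_um, ap_obj.d2_um, ap_obj.d3_um, ap_obj.d5_um,
                   ap_obj.a2_per_um_s, ap_obj.c0_um, ap_obj.c1, ap_obj.ip3_rest_um,
                   ap_obj.tau_ip3_s, ap_obj.glu_ip3_rate_um_per_s, ap_obj.k_glu_mm,
                   ap_obj.ca_release_threshold_nm, ap_obj.sigma_max,
                   ap_obj.clamp_value_nm * 1e-3, ap_obj.vesicle_drain_tau_s,
                   ap_obj.vesicle_recover_tau_s, ap_obj.vesicle_on_level,
                   ap_obj.vesicle_off_level])
    if config.has_astro:
        a0 = basal_state(ap_obj)
        astate = np.array([a0.ca_um, a0.ip3_um, a0.w, a0.vesicle, 0.0, 0.0])
    else:
        astate = np.zeros(6)

    v = assembly.v0.copy()
    gates = assembly.gates0.copy()
    chi = assembly.chi0.copy()
    r_ampa = np.zeros(nsyn)
    r_nmda = np.zeros(nsyn)
    h = np.zeros(len(assembly.sic_post))

    v_rec = np.empty((nrec, assembly.n_comp))
    glu_rec = np.empty((nrec, nsyn))
    h_rec = np.empty((nrec, max(len(assembly.sic_post), 0)))
    astro_rec = np.empty((nrec, 6))
    sigma_rec = np.empty(nrec)

    common = dict(
        parent=assembly.parent, gax=assembly.gax, gax_sum=assembly.gax_sum,
        cap=assembly.cap, area=assembly.area, gdens=assembly.gdens,
        vmin=vmin, dvinv=dvinv, xinf_tab=xinf_tab, dec_tab=dec_tab,
        e_na=E_NA, e_ca=E_CA, e_k=E_K, e_leak=E_LEAK, chi_sat=CHI_SAT,
        phi=assembly.pool_phi, chi_dec=np.exp(-dt / assembly.pool_tau_ms),
        chi_tau=assembly.pool_tau_ms,
        q_alpha_scale=Q_ALPHA_SCALE, q_alpha_max=Q_ALPHA_MAX, q_beta=Q_BETA,
        v=v, gates=gates, chi=chi,
        syn_pre=assembly.syn_pre, syn_post=assembly.syn_post,
        syn_gampa=assembly.syn_gampa, syn_gnmda=assembly.syn_gnmda,
        glu_gmax=glu_gmax, glu_vhalf=glu_vhalf, glu_kp=glu_kp,
        ampa_alpha=fp.ampa_alpha, ampa_beta=fp.ampa_beta,
        nmda_alpha=fp.nmda_alpha, nmda_beta=fp.nmda_beta,
        mg_fac=fp.mg_mm / fp.mg_k_mm, mg_gamma=fp.mg_gamma_per_mv,
        e_syn=fp.e_rev_mv, r_ampa=r_ampa, r_nmda=r_nmda,
        sic_post=assembly.sic_post, sic_g=assembly.sic_g,
        sic_dec=sic_dec, sic_gain=sic_gain,
        sic_clamp_h=np.int64(sic.clamp_h), sic_sub_rev=np.int64(sic.subtract_reversal),
        sic_erev=sic.e_rev_mv, h=h,
        astro_on=np.int64(config.has_astro),
        astro_clamp=np.int64(ap_obj.clamp_enabled), ap=ap, astate=astate,
        sense_syn=np.int64(0 if config.has_astro else -1), dt=dt,
    )

    t0 = time.perf_counter()
    if n_settle:
        scratch = (np.empty((1, assembly.n_comp)), np.empty((1, nsyn)),
                   np.empty((1, h.size)), np.empty((1, 6)), np.empty(1))
        status = _engine.run_network(**common, inj_ua=np.zeros(assembly.n_comp),
                                     n_steps=n_settle, rec_stride=n_settle + 1,
                                     v_rec=scratch[0], glu_rec=scratch[1],
                                     h_rec=scratch[2], astro_rec=scratch[3],
                                     sigma_rec=scratch[4])
        _raise_on_failure(status, assembly, v, "settle")

    status = _engine.run_network(**common, inj_ua=assembly.inj_ua,
                                 n_steps=n_steps, rec_stride=stride,
                                 v_rec=v_rec, glu_rec=glu_rec, h_rec=h_rec,
                                 astro_rec=astro_rec, sigma_rec=sigma_rec)
    _raise_on_failure(status, assembly, v, "stimulus")
    wall = time.perf_counter() - t0

    rows = []
    for name, m in assembly.morphologies.items():
        for c in m.compartments:
            rows.append({"cell": name, "local": c.index, "role": c.role_tag})
    comp_table = pd.DataFrame(rows)

    astro_df = None
    if config.has_astro:
        astro_df = pd.DataFrame(astro_rec, columns=[
            "ca_um", "ip3_um", "w", "vesicle", "sigma", "release_count"])

    t_ms = np.arange(nrec) * stride * dt
    stats = {"n_steps": n_steps + n_settle, "dt_ms": dt, "wall_s": round(wall, 3),
             "ode_count": assembly.ode_count}
    logger.info("simulated %s for %.1f s model time in %.1f s wall",
                config.scenario, config.duration_s, wall)
    return TraceSet(t_ms=t_ms, v=v_rec.T, comp_table=comp_table,
                    cell_offsets=dict(assembly.cell_offsets),
                    glu_mm=glu_rec.T, h=h_rec.T, sic_cells=list(assembly.sic_cells),
                    astro=astro_df, config=config, ode_count=assembly.ode_count,
                    solver_stats=stats)


def _raise_on_failure(status: int, assembly: Assembly, v: np.ndarray, phase: str):
    if status < 0:
        return
    bad = int(np.nanargmax(np.abs(np.nan_to_num(v, nan=np.inf, posinf=np.inf))))
    row = None
    for name, off in assembly.cell_offsets.items():
        m = assembly.morphologies[name]
        if off <= bad < off + m.n:
            row = f"{name} compartment {bad - off} ({m.compartments[bad - off].role_tag})"
            break
    raise RuntimeError(
        f"integration diverged during {phase}: worst-scaled state is {row}; "
        f"reduce dt_ms or check conductance overrides")
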