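"""Glutamate release, fast synaptic receptors, and astrocyte-evoked SICs.

Three couplings live here:

* the sigmoidal axon-voltage -> cleft-glutamate transform
  ``[g] = g_max / (1 + exp(-(V_axon - V_p)/K_p))`` with ``V_p`` expressed
  relative to rest,
* fast AMPA + synaptic-NMDA currents at dendritic spines, driven by cleft
  glutamate through first-order transmitter-binding kinetics with a
  voltage-dependent Mg2+ block on the NMDA component,
* the slow inward current through extrasynaptic NR1/NR2B NMDA receptors,
  ``I_SIC = g_NR2B * h * v_s`` with gating ``dh/dt = sigma/tau_1 - h/tau_2``,
  where ``sigma`` steps to 0.4 while the astrocyte releases glutamate.

The SIC conductance-voltage product is implemented exactly in its printed
form (driving force = v_s, no Mg2+ block); a conventional ``v_s - E_rev``
driving force is available behind a config flag, default off.  Anatomical
contact multiplicity (25 Schaffer contacts, 20 CA1-CA1 contacts) scales
one kinetic instance linearly rather than duplicating state: the model is
deterministic, so identical contacts would carry identical state anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import V_REST

__all__ = [
    "GlutamateReleaseParams",
    "SICParams",
    "FastSynapseParams",
    "SynapseSpec",
    "cleft_glutamate",
    "sic_gate_rhs",
    "sic_gate_solution",
    "sic_current",
    "receptor_rhs",
    "mg_block",
    "fast_synaptic_current",
]


@dataclass
class GlutamateReleaseParams:
    """Axon-voltage -> cleft glutamate sigmoid (half-max at V_p above rest)."""

    g_max_mm: float = 3.5        # maximum cleft glutamate, mM (3.5-4 admissible)
    v_p_mv: float = 72.0         # half-maximum voltage, mV relative to rest
    k_p_mv: float = 5.0          # steepness, mV
    v_rest_mv: float = V_REST    # absolute resting potential used for the shift

    def __post_init__(self):
        if not (3.5 <= self.g_max_mm <= 4.0):
            raise ValueError("g_max must lie in the admissible 3.5-4 mM range")
        if self.k_p_mv <= 0:
            raise ValueError("K_p must be positive")


def cleft_glutamate(v_axon_mv, params: GlutamateReleaseParams) -> np.ndarray | float:
    """Cleft glutamate (mM) from the absolute axonal membrane potential (mV)."""
    v = np.asarray(v_axon_mv, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("axon voltage must be finite")
    u = v - params.v_rest_mv  # rest-relative, same convention as V_p
    out = params.g_max_mm / (1.0 + np.exp(-(u - params.v_p_mv) / params.k_p_mv))
    return out if out.ndim else float(out)


@dataclass
class SICParams:
    """Extrasynaptic NR2B receptor (SIC) parameters."""

    g_nr2b_ns: float = 0.6          # single-site conductance, nS
    tau_1_ms: float = 92.3          # rise time constant
    tau_2_ms: float = 568.5         # decay time constant
    sigma_max: float = 0.4          # maximum eNMDAR open probability
    ca_release_threshold_nm: float = 200.0
    conductance_scale: float = 1.0  # 1 = normal, 2 = epileptiform
    clamp_h: bool = False           # optional clamp of h at 1 (default off, as printed)
    subtract_reversal: bool = False  # optional (v_s - E_rev) driving force, default off
    e_rev_mv: float = 0.0

    def __post_init__(self):
        if self.conductance_scale <= 0:
            raise ValueError("conductance_scale must be positive")
        if self.tau_1_ms <= 0 or self.tau_2_ms <= 0:
            raise ValueError("time constants must be positive")


def sic_gate_rhs(h: float, sigma: float, params: SICParams) -> float:
    """dh/dt (1/ms) of the eNMDAR gating variable: sigma/tau_1 - h/tau_2."""
    return sigma / params.tau_1_ms - h / params.tau_2_ms


def sic_gate_solution(t_ms, h0: float, sigma: float, params: SICParams):
    """Closed-form solution of the gate ODE under constant sigma (for checks)."""
    t = np.asarray(t_ms, dtype=float)
    h_inf = sigma * params.tau_2_ms / params.tau_1_ms
    return h_inf + (h0 - h_inf) * np.exp(-t / params.tau_2_ms)


def sic_current(h: float, v_s_mv: float, params: SICParams):
    """SIC in nA: conductance_scale * g_NR2B * h * v_s (as printed).

    nS * mV = pA, hence the 1e-3 factor.  With the absolute-mV convention a
    resting spine (v_s < 0) yields a negative, i.e. inward, current.
    """
    h_eff = np.minimum(h, 1.0) if params.clamp_h else h
    drive = np.asarray(v_s_mv, dtype=float) - (params.e_rev_mv if params.subtract_reversal else 0.0)
    out = params.conductance_scale * params.g_nr2b_ns * np.asarray(h_eff) * drive * 1e-3
    return out if np.ndim(out) else float(out)


@dataclass
class FastSynapseParams:
    """AMPA + synaptic NMDA kinetics (first-order transmitter binding).

    Per-contact peak conductances in nS; binding/unbinding rates follow the
    standard kinetic-synapse constants (alpha in 1/(mM ms), beta in 1/ms).
    The NMDA component carries the conventional sigmoidal Mg2+ block.
    """

    g_ampa_ns: float = 0.45
    g_nmda_ns: float = 0.25
    e_rev_mv: float = 0.0
    ampa_alpha: float = 1.1
    ampa_beta: float = 0.19
    nmda_alpha: float = 0.072
    nmda_beta: float = 0.0066
    mg_mm: float = 1.0
    mg_gamma_per_mv: float = 0.062
    mg_k_mm: float = 3.57


def receptor_rhs(r, glu_mm, alpha, beta):
    """Bound-receptor fraction kinetics dr/dt = alpha*[glu]*(1-r) - beta*r."""
    return alpha * glu_mm * (1.0 - np.asarray(r, dtype=float)) - beta * np.asarray(r, dtype=float)


def mg_block(v_mv, params: FastSynapseParams):
    """Voltage-dependent Mg2+ unblock fraction of the NMDA conductance."""
    v = np.asarray(v_mv, dtype=float)
    out = 1.0 / (1.0 + np.exp(-params.mg_gamma_per_mv * v) * params.mg_mm / params.mg_k_mm)
    return out if out.ndim else float(out)


def fast_synaptic_current(r_ampa, r_nmda, v_mv, params: FastSynapseParams,
                          multiplicity: int = 1):
    """Pooled AMPA + NMDA current (nA, outward positive) at the postsynaptic site."""
    drive = np.asarray(v_mv, dtype=float) - params.e_rev_mv
    g_ampa = params.g_ampa_ns * np.asarray(r_ampa)
    g_nmda = params.g_nmda_ns * np.asarray(r_nmda) * mg_block(v_mv, params)
    out = multiplicity * (g_ampa + g_nmda) * drive * 1e-3  # nS*mV = pA -> nA
    return out if np.ndim(out) else float(out)


@dataclass
class SynapseSpec:
    """One anatomical connection (pooled over its contact multiplicity)."""

    pre_cell: str          # e.g. "CA3", "CA1_1"
    pre_comp: int          # release-site (axonal) compartment index
    post_cell: str
    post_comp: int         # spine head / dendritic target compartment index
    multiplicity: int = 1
    receptors: str = "fast"  # {"fast", "eNMDAR"}
    fast_params: FastSynapseParams = field(default_factory=FastSynapseParams)

    def __post_init__(self):
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be a positive count")
        if self.receptors not in ("fast", "eNMDAR"):
            raise ValueError(f"unknown receptor complement {self.receptors!r}")
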