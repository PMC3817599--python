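"""Astrocytic Ca2+ dynamics, the 200 nM release gate, and the clamp control.

The cytosolic Ca2+ / ER exchange follows the two-variable Li-Rinzel
reduction of the IP3-receptor model (channel flux gated by IP3 and Ca2+
with slow Ca-dependent inactivation ``w``, SERCA pump, ER leak), driven by
glutamate sensed at the Schaffer-collateral cleft through a saturating
IP3-production term.  Whenever cytosolic Ca2+ exceeds the release
threshold (200 nM) the astrocyte releases glutamate onto the
extrasynaptic NR2B receptors, raising the SIC gate factor sigma to its
maximum open probability (0.4, strict inequality at the threshold).

Gliotransmitter exocytosis is represented deterministically: a docked
vesicle pool ``y`` drains quickly while release is ongoing and recovers
slowly otherwise, with on/off hysteresis.  Within one suprathreshold Ca2+
epoch of the default scenario this machinery produces two discrete release
episodes -- and hence two SICs -- before the epoch ends, matching the
reported phenomenology; a release-event counter is kept in the trace.

In clamp mode (the gliotransmission-incapacitated control) cytosolic Ca2+
is held at the clamp value (default 100 nM, below threshold) and all
astrocytic derivatives vanish, so sigma stays 0 and no SIC is ever
generated.

Units: Ca2+ and IP3 in uM internally (thresholds are stated in nM at the
API), rate constants per second; the network engine converts to its ms
step internally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["AstrocyteParams", "AstrocyteState", "release_gate", "astro_rhs",
           "update_release_machinery", "basal_state"]


@dataclass
class AstrocyteParams:
    # Li-Rinzel / IP3R constants
    v1_per_s: float = 6.0       # max channel flux rate
    v2_per_s: float = 0.11      # ER leak rate
    v3_um_per_s: float = 0.9    # max SERCA pump rate
    k3_um: float = 0.1          # pump activation
    d1_um: float = 0.13         # IP3 binding
    d2_um: float = 1.049        # Ca inactivation binding
    d3_um: float = 0.9434       # IP3 binding (inactivated receptor)
    d5_um: float = 0.08234      # Ca activation binding
    a2_per_um_s: float = 0.2    # inactivation rate constant
    c0_um: float = 2.0          # total free Ca per cytosol volume
    c1: float = 0.185           # ER/cytosol volume ratio
    # IP3 metabolism and glutamate coupling
    ip3_rest_um: float = 0.16
    tau_ip3_s: float = 14.0
    # glutamate->IP3 gain, calibrated so the first Ca2+ oscillation (first
    # 200 nM crossing) arrives ~10.5 s after CA3 activity onset; cleft
    # glutamate is pulsatile (sub-percent duty cycle), hence the large gain
    glu_ip3_rate_um_per_s: float = 19.0
    k_glu_mm: float = 0.3
    # release gate / clamp
    sigma_max: float = 0.4
    ca_release_threshold_nm: float = 200.0
    clamp_enabled: bool = False
    clamp_value_nm: float = 100.0
    # deterministic exocytosis machinery (docked-pool drain/recover, hysteresis)
    vesicle_drain_tau_s: float = 0.03
    vesicle_recover_tau_s: float = 1.8
    vesicle_on_level: float = 0.90
    vesicle_off_level: float = 0.20

    def __post_init__(self):
        if self.clamp_enabled and self.clamp_value_nm >= self.ca_release_threshold_nm:
            raise ValueError("clamp value must stay below the release threshold")


@dataclass
class AstrocyteState:
    ca_um: float = 0.0718
    ip3_um: float = 0.16
    w: float = 0.958          # IP3R inactivation gate, in [0, 1]
    vesicle: float = 1.0      # docked-pool availability, in [0, 1]
    releasing: bool = False
    release_count: int = 0

    @property
    def ca_nm(self) -> float:
        return self.ca_um * 1e3


def release_gate(ca_nm: float, params: AstrocyteParams) -> float:
    """sigma = sigma_max when Ca2+ is strictly above threshold, else 0."""
    ca = np.asarray(ca_nm, dtype=float)
    if np.any(ca < 0):
        raise ValueError("Ca2+ concentration cannot be negative")
    out = np.where(ca > params.ca_release_threshold_nm, params.sigma_max, 0.0)
    return out if out.ndim else float(out)


def _lr_fluxes(ca, ip3, w, p: AstrocyteParams):
    ca_er = (p.c0_um - ca) / p.c1
    m_inf = ip3 / (ip3 + p.d1_um)
    n_inf = ca / (ca + p.d5_um)
    j_chan = p.c1 * p.v1_per_s * (m_inf * n_inf * w) ** 3 * (ca_er - ca)
    j_leak = p.c1 * p.v2_per_s * (ca_er - ca)
    j_pump = p.v3_um_per_s * ca * ca / (ca * ca + p.k3_um * p.k3_um)
    return j_chan, j_leak, j_pump


def astro_rhs(state: AstrocyteState, sensed_glutamate_mm: float,
              params: AstrocyteParams):
    """Time derivatives (per second) of (Ca2+, IP3, w).

    In clamp mode the Ca2+ (and gate) derivatives are identically zero;
    the clamped concentration itself is enforced by the caller/integrator.
    """
    if params.clamp_enabled:
        return 0.0, 0.0, 0.0
    ca, ip3, w = state.ca_um, state.ip3_um, state.w
    j_chan, j_leak, j_pump = _lr_fluxes(ca, ip3, w, params)
    dca = j_chan + j_leak - j_pump
    q2 = params.d2_um * (ip3 + params.d1_um) / (ip3 + params.d3_um)
    dw = params.a2_per_um_s * (q2 * (1.0 - w) - w * ca)
    production = params.glu_ip3_rate_um_per_s * sensed_glutamate_mm / (
        sensed_glutamate_mm + params.k_glu_mm)
    dip3 = (params.ip3_rest_um - ip3) / params.tau_ip3_s + production
    return dca, dip3, dw


def update_release_machinery(state: AstrocyteState, dt_s: float,
                             params: AstrocyteParams) -> float:
    """Advance the docked-vesicle pool and release flag; return effective sigma.

    Release starts when Ca2+ is above threshold and the pool has recovered
    past ``vesicle_on_level``; it stops when the pool drains below
    ``vesicle_off_level`` or Ca2+ falls back below threshold.  The returned
    sigma is ``sigma_max`` during an ongoing release episode, else 0.
    """
    gate_open = release_gate(state.ca_nm, params) > 0.0
    if state.releasing:
        dy = (-state.vesicle / params.vesicle_drain_tau_s
              + (1.0 - state.vesicle) / params.vesicle_recover_tau_s)
        state.vesicle = min(1.0, max(0.0, state.vesicle + dt_s * dy))
        if state.vesicle < params.vesicle_off_level or not gate_open:
            state.releasing = False
    else:
        state.vesicle = min(1.0, state.vesicle + dt_s * (1.0 - state.vesicle)
                            / params.vesicle_recover_tau_s)
        if gate_open and state.vesicle >= params.vesicle_on_level:
            state.releasing = True
            state.release_count += 1
    return params.sigma_max if state.releasing else 0.0


def basal_state(params: AstrocyteParams, sensed_glutamate_mm: float = 0.0,
                t_max_s: float = 600.0) -> AstrocyteState:
    """Relax the astrocyte to its resting point under constant drive.

    With zero sensed glutamate the basal Ca2+ fixed point sits well below
    the 200 nM release threshold.
    """
    if params.clamp_enabled:
        return AstrocyteState(ca_um=params.clamp_value_nm * 1e-3,
                              ip3_um=params.ip3_rest_um, w=0.9, vesicle=1.0)
    st = AstrocyteState()
    dt = 0.01
    for _ in range(int(t_max_s / dt)):
        dca, dip3, dw = astro_rhs(st, sensed_glutamate_mm, params)
        st = replace(st, ca_um=st.ca_um + dt * dca, ip3_um=st.ip3_um + dt * dip3,
                     w=min(1.0, max(0.0, st.w + dt * dw)))
    return st
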