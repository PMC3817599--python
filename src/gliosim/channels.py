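"""Hodgkin-Huxley channel kinetics of the Traub hippocampal pyramidal-cell family.

The CA3 and CA1 compartmental neurons share a single family of six active
conductances plus leak: fast sodium (Na), high-threshold calcium (Ca),
delayed-rectifier potassium (K_DR), transient A-type potassium (K_A),
fast Ca- and voltage-dependent potassium (K_C) and slow Ca-dependent
after-hyperpolarisation potassium (K_AHP).  Rate functions follow the
Traub-1991 convention: they are written on the rest-relative voltage
``u = V - V_REST`` (``V_REST = -60 mV`` absolute), with rates in 1/ms.

Voltage convention
------------------
All public functions take the *absolute* membrane potential in mV.  The
rest-relative shift is applied internally, so reversal potentials are
absolute too (E_Na = +55 mV, E_Ca = +80 mV, E_K = -75 mV, E_leak = -60 mV).

Calcium pool
------------
Each compartment carries a dimensionless Ca pool ``chi`` (Traub's
concentration units) with first-order decay,

    d(chi)/dt = -phi * I_Ca_density - chi / tau_chi,

where ``I_Ca_density`` is in uA/cm^2.  ``chi`` saturates the K_C
conductance through the factor min(chi / CHI_SAT, 1) and drives the
K_AHP activation rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "V_REST",
    "E_NA",
    "E_CA",
    "E_K",
    "E_LEAK",
    "CHI_SAT",
    "CA_POOL_PHI",
    "CA_POOL_TAU_MS",
    "GATE_NAMES",
    "ChannelKinetics",
    "CHANNELS",
    "gate_rates",
    "rates",
    "steady_state",
    "time_constant",
    "open_fraction",
    "ionic_current",
    "channel_table",
    "channels_from_table",
]

V_REST = -60.0  # mV, absolute resting reference of the Traub convention

E_NA = V_REST + 115.0   # +55 mV
E_CA = V_REST + 140.0   # +80 mV
E_K = V_REST - 15.0     # -75 mV
E_LEAK = V_REST         # -60 mV

#: K_C saturation level of the Ca pool (Traub's chi units).
CHI_SAT = 250.0
#: K_AHP activation-rate law: alpha_q = min(Q_ALPHA_SCALE * chi, Q_ALPHA_MAX).
Q_ALPHA_SCALE = 2e-5
Q_ALPHA_MAX = 0.01
#: K_AHP deactivation rate (1/ms).  The parent model family publishes
#: 0.001/ms; the default here (~385 ms sAHP decay, within the physiological
#: range) is the value that lets the CA3 cell express its burst rhythm --
#: see docs/methods.md.
Q_BETA = 2.6e-3
#: Ca-pool influx factor: d(chi)/dt includes -phi * I_Ca [uA/cm^2].
CA_POOL_PHI = 0.13
#: Ca-pool decay time constant (ms); decay rate 0.075 / ms.
CA_POOL_TAU_MS = 1.0 / 0.075

GATE_NAMES = ("m", "h", "n", "a", "b", "s", "c", "q")


def _vtrap(y, k):
    """Evaluate ``y / (exp(y/k) - 1)`` with the removable singularity at y=0.

    The analytic limit at y -> 0 is k; a second-order Taylor expansion
    ``k - y/2 + y^2/(12 k)`` is used in a narrow window around it.
    """
    y = np.asarray(y, dtype=float)
    small = np.abs(y) < 1e-7
    safe = np.where(small, 1.0, y)
    out = np.where(small, k - y / 2.0 + y * y / (12.0 * k), safe / np.expm1(safe / k))
    return out if out.ndim else float(out)


# -- rate functions on u = V - V_REST (1/ms) --------------------------------

def _alpha_m(u, chi=0.0):
    return 0.32 * _vtrap(13.1 - u, 4.0)


def _beta_m(u, chi=0.0):
    return 0.28 * _vtrap(u - 40.1, 5.0)


def _alpha_h(u, chi=0.0):
    return 0.128 * np.exp((17.0 - u) / 18.0)


def _beta_h(u, chi=0.0):
    return 4.0 / (1.0 + np.exp((40.0 - u) / 5.0))


def _alpha_n(u, chi=0.0):
    return 0.016 * _vtrap(35.1 - u, 5.0)


def _beta_n(u, chi=0.0):
    return 0.25 * np.exp((20.0 - u) / 40.0)


def _alpha_a(u, chi=0.0):
    return 0.02 * _vtrap(13.1 - u, 10.0)


def _beta_a(u, chi=0.0):
    return 0.0175 * _vtrap(u - 40.1, 10.0)


def _alpha_b(u, chi=0.0):
    return 0.0016 * np.exp((-13.0 - u) / 18.0)


def _beta_b(u, chi=0.0):
    return 0.05 / (1.0 + np.exp((10.1 - u) / 5.0))


def _alpha_s(u, chi=0.0):
    return 1.6 / (1.0 + np.exp(-0.072 * (u - 65.0)))


def _beta_s(u, chi=0.0):
    return 0.02 * _vtrap(u - 51.1, 5.0)


def _alpha_c(u, chi=0.0):
    u = np.asarray(u, dtype=float)
    low = np.exp((u - 10.0) / 11.0 - (u - 6.5) / 27.0) / 18.975
    high = 2.0 * np.exp((6.5 - u) / 27.0)
    out = np.where(u <= 50.0, low, high)
    return out if out.ndim else float(out)


def _beta_c(u, chi=0.0):
    u = np.asarray(u, dtype=float)
    out = np.where(u <= 50.0, 2.0 * np.exp((6.5 - u) / 27.0) - _alpha_c(u), 0.0)
    return out if out.ndim else float(out)


def _alpha_q(u, chi=0.0):
    chi = np.asarray(chi, dtype=float)
    out = np.minimum(Q_ALPHA_SCALE * chi, Q_ALPHA_MAX)
    return out if out.ndim else float(out)


def _beta_q(u, chi=0.0):
    return np.full_like(np.asarray(u, dtype=float), Q_BETA) if np.ndim(u) else Q_BETA


_GATE_RATES = {
    "m": (_alpha_m, _beta_m),
    "h": (_alpha_h, _beta_h),
    "n": (_alpha_n, _beta_n),
    "a": (_alpha_a, _beta_a),
    "b": (_alpha_b, _beta_b),
    "s": (_alpha_s, _beta_s),
    "c": (_alpha_c, _beta_c),
    "q": (_alpha_q, _beta_q),
}


@dataclass(frozen=True)
class ChannelKinetics:
    """One conductance: its gates (with exponents) and reversal potential.

    ``gates`` maps gate name -> integer exponent in the open-fraction
    product.  ``ca_saturating`` marks the K_C-style multiplicative
    min(chi/CHI_SAT, 1) factor.
    """

    name: str
    e_rev: float
    gates: dict = field(default_factory=dict)
    ca_saturating: bool = False

    def open_fraction(self, gating: dict, chi=0.0):
        f = 1.0
        for g, p in self.gates.items():
            f = f * np.asarray(gating[g], dtype=float) ** p
        if self.ca_saturating:
            f = f * np.minimum(np.asarray(chi, dtype=float) / CHI_SAT, 1.0)
        return f


CHANNELS = {
    "Na": ChannelKinetics("Na", E_NA, {"m": 2, "h": 1}),
    "Ca": ChannelKinetics("Ca", E_CA, {"s": 2}),
    "K_DR": ChannelKinetics("K_DR", E_K, {"n": 1}),
    "K_A": ChannelKinetics("K_A", E_K, {"a": 1, "b": 1}),
    "K_C": ChannelKinetics("K_C", E_K, {"c": 1}, ca_saturating=True),
    "K_AHP": ChannelKinetics("K_AHP", E_K, {"q": 1}),
    "leak": ChannelKinetics("leak", E_LEAK, {}),
}


def gate_rates(gate: str, v_mv, chi=0.0):
    """Forward/backward rates (1/ms) of one gating variable at absolute V (mV)."""
    if gate not in _GATE_RATES:
        raise KeyError(f"unknown gate {gate!r}; known: {sorted(_GATE_RATES)}")
    v = np.asarray(v_mv, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("membrane potential must be finite")
    u = v - V_REST
    af, bf = _GATE_RATES[gate]
    return af(u, chi), bf(u, chi)


def rates(channel: ChannelKinetics | str, v_mv, chi=0.0):
    """Per-gate (alpha, beta) map of a channel at absolute V (mV)."""
    ch = CHANNELS[channel] if isinstance(channel, str) else channel
    return {g: gate_rates(g, v_mv, chi) for g in ch.gates}


def steady_state(gate: str, v_mv, chi=0.0):
    a, b = gate_rates(gate, v_mv, chi)
    return a / (a + b)


def time_constant(gate: str, v_mv, chi=0.0):
    a, b = gate_rates(gate, v_mv, chi)
    return 1.0 / (a + b)


def open_fraction(channel: ChannelKinetics | str, gating: dict, chi=0.0):
    ch = CHANNELS[channel] if isinstance(channel, str) else channel
    return ch.open_fraction(gating, chi)


def ionic_current(channel: ChannelKinetics | str, gating: dict, v_mv,
                  density_ms_cm2: float, area_cm2: float, chi=0.0):
    """Channel current in nA, outward positive.

    I = density * area * (gating product) * (V - E_rev); mS * mV = uA,
    hence the factor 1000 to nA.
    """
    ch = CHANNELS[channel] if isinstance(channel, str) else channel
    f = ch.open_fraction(gating, chi)
    return density_ms_cm2 * area_cm2 * f * (np.asarray(v_mv, dtype=float) - ch.e_rev) * 1e3


def channel_table() -> dict:
    """Channel parameters as a plain mapping (config-file form)."""
    return {
        name: {
            "e_rev_mv": ch.e_rev,
            "gates": dict(ch.gates),
            "ca_saturating": ch.ca_saturating,
        }
        for name, ch in CHANNELS.items()
    }


def channels_from_table(table: dict) -> dict:
    """Rebuild the channel registry from :func:`channel_table` output."""
    return {
        name: ChannelKinetics(name, spec["e_rev_mv"], dict(spec["gates"]),
                              bool(spec.get("ca_saturating", False)))
        for name, spec in table.items()
    }
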