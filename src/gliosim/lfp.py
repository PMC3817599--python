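"""Extracellular field potential at a virtual electrode, PSD and burst metrics.

The electrode senses the superposed volume-conducted contributions of every
CA1 compartment's transmembrane current.  The CA1 somata sit 25 um apart
along the cell row and the electrode sits 25 um beyond the soma of CA1
neuron 4.  Each compartment contributes either as a point source,

    Phi = rho_c * I_c / (4 * pi * r_c),

or through the standard line-source kernel along its somato-dendritic axis
(which degrades to the point form when the compartment is short compared
with its distance).  Extracellular resistivity is region-specific: 643
Ohm*cm at somata and proximal apical dendrites, 260 Ohm*cm basal, 287
Ohm*cm distal apical.  Axon and initial-segment compartments contribute
nothing (myelinated axon assumption).

Spectral analysis is a magnitude-squared FFT of the full analysis window
(optionally Welch-averaged); burst analysis segments event trains at an
inter-event-interval threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .morphology import LFP_EXCLUDED_ROLES, Morphology
from .network import TraceSet, detect_spikes

__all__ = [
    "ElectrodeGeometry", "LFPConfig", "SpectrumResult", "BurstMetrics",
    "build_geometry", "field_potential", "compute_lfp", "psd",
    "burst_metrics", "lfp_episodes",
]

RHO_SOMA_PROXIMAL_APICAL = 643.0   # Ohm*cm
RHO_BASAL = 260.0
RHO_DISTAL_APICAL = 287.0
#: apical compartments within this path distance of the soma count as proximal
PROXIMAL_APICAL_MAX_UM = 360.0

CA1_SPACING_UM = 25.0
ELECTRODE_OFFSET_UM = 25.0


@dataclass
class LFPConfig:
    rho_soma_proximal: float = RHO_SOMA_PROXIMAL_APICAL
    rho_basal: float = RHO_BASAL
    rho_distal_apical: float = RHO_DISTAL_APICAL
    excluded_roles: tuple = LFP_EXCLUDED_ROLES
    source_model: str = "line_source"   # or "point_source"

    def __post_init__(self):
        if min(self.rho_soma_proximal, self.rho_basal, self.rho_distal_apical) <= 0:
            raise ValueError("resistivities must be strictly positive")
        if self.source_model not in ("line_source", "point_source"):
            raise ValueError(f"unknown source model {self.source_model!r}")
        if not set(LFP_EXCLUDED_ROLES) <= set(self.excluded_roles):
            raise ValueError("IS and axon compartments are always LFP-excluded")


@dataclass
class ElectrodeGeometry:
    """Compartment source geometry for one stack of cells.

    ``centers_um``/``starts_um``/``ends_um`` are (n, 3) coordinates of each
    included compartment (segment endpoints along the somato-dendritic
    axis), ``rho_ohm_cm`` the local extracellular resistivity and
    ``electrode_um`` the recording position.
    """

    centers_um: np.ndarray
    starts_um: np.ndarray
    ends_um: np.ndarray
    rho_ohm_cm: np.ndarray
    include: np.ndarray               # bool mask aligned with the current rows
    electrode_um: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def distances_um(self) -> np.ndarray:
        r = np.linalg.norm(self.centers_um - self.electrode_um, axis=1)
        if np.any(r[self.include] <= 0):
            raise ValueError("electrode coincides with a contributing compartment")
        return r


def _cell_layout(morph: Morphology, x_um: float):
    """Segment endpoints of one cell: soma at (x, 0, 0), apical +y, basal/axon -y.

    Path distance accumulates along the tree; spine heads sit beside their
    parent (0.5 um off-axis) so their distance to the electrode stays finite.
    """
    n = morph.n
    centers = np.zeros((n, 3))
    starts = np.zeros((n, 3))
    ends = np.zeros((n, 3))
    path = np.zeros(n)  # path distance of compartment center from soma center
    for i, c in enumerate(morph.compartments):
        if c.parent is None:
            half = c.length_um / 2.0
            starts[i] = (x_um, -half, 0.0)
            ends[i] = (x_um, half, 0.0)
            centers[i] = (x_um, 0.0, 0.0)
            continue
        sign = 1.0 if c.role_tag == "apical_dendrite" else -1.0
        if c.role_tag == "spine_head":
            centers[i] = centers[c.parent] + (0.5, 0.0, 0.0)
            starts[i] = centers[i]
            ends[i] = centers[i]
            path[i] = path[c.parent]
            continue
        parent = morph.compartments[c.parent]
        base = path[c.parent] + parent.length_um / 2.0 if parent.role_tag != "spine_head" \
            else path[c.parent]
        if parent.role_tag == "soma":
            base = parent.length_um / 2.0
        path[i] = base + c.length_um / 2.0
        y0, y1 = sign * base, sign * (base + c.length_um)
        starts[i] = (x_um, y0, 0.0)
        ends[i] = (x_um, y1, 0.0)
        centers[i] = (x_um, (y0 + y1) / 2.0, 0.0)
    return centers, starts, ends, path


def _cell_rho(morph: Morphology, path_um: np.ndarray, config: LFPConfig) -> np.ndarray:
    rho = np.empty(morph.n)
    for i, c in enumerate(morph.compartments):
        role = c.role_tag
        if role == "spine_head":
            role = morph.compartments[c.parent].role_tag
            dist = path_um[c.parent]
        else:
            dist = path_um[i]
        if role == "soma":
            rho[i] = config.rho_soma_proximal
        elif role == "apical_dendrite":
            rho[i] = config.rho_soma_proximal if dist <= PROXIMAL_APICAL_MAX_UM \
                else config.rho_distal_apical
        elif role == "basal_dendrite":
            rho[i] = config.rho_basal
        else:  # IS / axon: excluded anyway, keep the somatic value
            rho[i] = config.rho_soma_proximal
    return rho


def build_geometry(morph: Morphology, n_cells: int = 4,
                   spacing_um: float = CA1_SPACING_UM,
                   electrode_offset_um: float = ELECTRODE_OFFSET_UM,
                   config: LFPConfig | None = None) -> ElectrodeGeometry:
    """Default row geometry: ``n_cells`` CA1 cells spaced along x, electrode
    ``electrode_offset_um`` beyond the last soma at dendritic mid-level."""
    config = config or LFPConfig()
    centers, starts, ends, rho, include = [], [], [], [], []
    for k in range(n_cells):
        c, s, e, path = _cell_layout(morph, k * spacing_um)
        centers.append(c)
        starts.append(s)
        ends.append(e)
        rho.append(_cell_rho(morph, path, config))
        include.append(np.array([cc.role_tag not in config.excluded_roles
                                 for cc in morph.compartments]))
    electrode = np.array([(n_cells - 1) * spacing_um + electrode_offset_um, 0.0, 0.0])
    return ElectrodeGeometry(
        centers_um=np.vstack(centers), starts_um=np.vstack(starts),
        ends_um=np.vstack(ends), rho_ohm_cm=np.concatenate(rho),
        include=np.concatenate(include), electrode_um=electrode)


def field_potential(currents_na: np.ndarray, geometry: ElectrodeGeometry,
                    config: LFPConfig | None = None) -> np.ndarray:
    """LFP trace (volts) from per-compartment transmembrane currents (nA).

    ``currents_na`` has shape (n_sources, n_times) aligned with the
    geometry rows; excluded compartments are masked out here regardless of
    their values.
    """
    config = config or LFPConfig()
    cur = np.atleast_2d(np.asarray(currents_na, dtype=float))
    if cur.shape[0] != geometry.centers_um.shape[0]:
        raise ValueError("currents rows must align with geometry compartments")
    mask = geometry.include
    rho_m = geometry.rho_ohm_cm * 1e-2           # Ohm*cm -> Ohm*m
    if config.source_model == "point_source":
        r_m = geometry.distances_um() * 1e-6
        w = np.where(mask, rho_m / (4.0 * np.pi * r_m), 0.0)
    else:
        w = np.zeros(cur.shape[0])
        e = geometry.electrode_um
        for i in np.flatnonzero(mask):
            a, b = geometry.starts_um[i], geometry.ends_um[i]
            ds = np.linalg.norm(b - a)
            if ds < 1e-9:  # degenerate segment: point source
                r = np.linalg.norm(geometry.centers_um[i] - e)
                if r <= 0:
                    raise ValueError("electrode coincides with a source")
                w[i] = rho_m[i] / (4.0 * np.pi * r * 1e-6)
                continue
            axis = (b - a) / ds
            # signed axial distance from electrode projection to segment ends
            hdist = float(np.dot(a - e, axis))
            ldist = hdist + ds
            r_perp2 = float(np.dot(a - e, a - e) - hdist ** 2)
            num = np.sqrt(hdist ** 2 + r_perp2) - hdist
            den = np.sqrt(ldist ** 2 + r_perp2) - ldist
            if den <= 0 or num <= 0:
                raise ValueError("electrode lies on a source segment axis")
            w[i] = rho_m[i] / (4.0 * np.pi * ds * 1e-6) * np.log(num / den)
    return (w[:, None] * cur * 1e-9).sum(axis=0)  # nA -> A


def compute_lfp(traces: TraceSet, morph: Morphology,
                geometry: ElectrodeGeometry | None = None,
                config: LFPConfig | None = None) -> np.ndarray:
    """LFP (volts) of a network run: CA1 cells only, IS/axon excluded."""
    config = config or LFPConfig()
    cells = [c for c in traces.cell_offsets if c.startswith("CA1")]
    geometry = geometry or build_geometry(morph, n_cells=len(cells), config=config)
    cur = np.vstack([traces.transmembrane_currents_na(c, morph) for c in cells])
    return field_potential(cur, geometry, config)


@dataclass
class SpectrumResult:
    freq_hz: np.ndarray
    power: np.ndarray                  # V^2/Hz (one-sided density)
    peak_frequency_hz: float
    band_powers: dict                  # name -> integrated power in band
    delta_fraction: float              # delta power / total analysed power

    def band_fraction(self, name: str) -> float:
        total = sum(self.band_powers.values())
        return self.band_powers[name] / total if total > 0 else np.nan


DEFAULT_BANDS = {"delta": (0.5, 4.0), "theta": (4.0, 11.0), "beta_plus": (11.0, 50.0)}


def psd(x: np.ndarray, fs_hz: float, analysis_band=(0.25, 50.0),
        bands: dict | None = None, nperseg: int | None = None,
        window: str = "boxcar") -> SpectrumResult:
    """Power spectral density with peak and band summaries.

    The default estimator is the magnitude-squared FFT of the complete
    window (periodogram); passing ``nperseg`` switches to Welch segment
    averaging.  The peak frequency is the argmax within ``analysis_band``.
    """
    x = np.asarray(x, dtype=float)
    if nperseg is not None:
        if x.size < nperseg:
            raise ValueError("trace shorter than one analysis segment")
        f, p = signal.welch(x, fs=fs_hz, window="hann", nperseg=nperseg)
    else:
        if x.size < 2:
            raise ValueError("trace too short for spectral analysis")
        f, p = signal.periodogram(x, fs=fs_hz, window=window, detrend="constant")
    bands = dict(bands or DEFAULT_BANDS)
    lo, hi = analysis_band
    sel = (f >= lo) & (f <= hi)
    if not np.any(sel):
        raise ValueError("analysis band contains no frequency bins")
    peak = float(f[sel][np.argmax(p[sel])])
    df = f[1] - f[0] if f.size > 1 else 1.0
    band_powers = {name: float(p[(f >= b0) & (f < b1)].sum() * df)
                   for name, (b0, b1) in bands.items()}
    total = float(p[sel].sum() * df)
    d0, d1 = bands.get("delta", (0.5, 4.0))
    delta = float(p[sel & (f >= d0) & (f < d1)].sum() * df)
    return SpectrumResult(freq_hz=f, power=p, peak_frequency_hz=peak,
                          band_powers=band_powers,
                          delta_fraction=delta / total if total > 0 else np.nan)


@dataclass
class BurstMetrics:
    n_bursts: int
    intraburst_hz: float               # mean of (spikes-1)/span over multi-spike bursts
    repetition_hz: float | None        # 1 / mean inter-burst-onset interval
    durations_ms: list
    onsets_ms: list
    flags: list = field(default_factory=list)


def burst_metrics(event_times_ms, gap_ms: float = 100.0) -> BurstMetrics:
    """Segment an event train into bursts at an inter-event-interval gap."""
    t = np.sort(np.asarray(event_times_ms, dtype=float))
    if t.size == 0:
        raise ValueError("event list is empty")
    flags = []
    if t.size == 1:
        return BurstMetrics(1, np.nan, None, [0.0], [float(t[0])],
                            ["single event: metrics undefined"])
    splits = np.flatnonzero(np.diff(t) > gap_ms) + 1
    bursts = np.split(t, splits)
    onsets = [float(b[0]) for b in bursts]
    durations = [float(b[-1] - b[0]) for b in bursts]
    rates = [(len(b) - 1) / (b[-1] - b[0]) * 1e3 for b in bursts if len(b) > 1]
    if not rates:
        flags.append("no multi-event burst: intraburst frequency undefined")
        intra = np.nan
    else:
        intra = float(np.mean(rates))
    if len(onsets) < 2:
        flags.append("single burst: repetition rate undefined")
        rep = None
    else:
        rep = float(1e3 / np.mean(np.diff(onsets)))
    return BurstMetrics(len(bursts), intra, rep, durations, onsets, flags)


def lfp_episodes(lfp_v: np.ndarray, fs_hz: float, highpass_hz: float = 10.0,
                 smooth_ms: float = 50.0, threshold_frac: float = 0.1,
                 merge_gap_ms: float = 150.0, min_duration_ms: float = 50.0):
    """High-frequency LFP episodes by an amplitude-envelope threshold.

    The trace is high-pass filtered, rectified and smoothed; contiguous
    stretches above ``threshold_frac`` of the envelope maximum (merged
    across gaps shorter than ``merge_gap_ms``) are episodes.  Returns a
    list of (onset_ms, offset_ms) pairs.
    """
    x = np.asarray(lfp_v, dtype=float)
    sos = signal.butter(4, highpass_hz, btype="highpass", fs=fs_hz, output="sos")
    y = np.abs(signal.sosfiltfilt(sos, x - x.mean()))
    win = max(1, int(round(smooth_ms * fs_hz / 1e3)))
    env = np.convolve(y, np.ones(win) / win, mode="same")
    thr = threshold_frac * env.max()
    above = env > thr
    if not np.any(above):
        return []
    idx = np.flatnonzero(above)
    gaps = np.flatnonzero(np.diff(idx) > merge_gap_ms * fs_hz / 1e3)
    starts = np.concatenate(([idx[0]], idx[gaps + 1]))
    stops = np.concatenate((idx[gaps], [idx[-1]]))
    half_gap = int(round(merge_gap_ms * fs_hz / 2e3))
    out = []
    for s0, s1 in zip(starts, stops):
        # refine the span against the episode's own peak so weaker episodes
        # are not truncated by the globally strongest one
        lo = max(0, s0 - half_gap)
        hi = min(env.size, s1 + half_gap + 1)
        local = env[lo:hi]
        local_thr = threshold_frac * local.max()
        above_l = np.flatnonzero(local > local_thr)
        t0 = (lo + above_l[0]) / fs_hz * 1e3
        t1 = (lo + above_l[-1]) / fs_hz * 1e3
        if t1 - t0 >= min_duration_ms:
            out.append((t0, t1))
    return out


def spike_synchrony(traces: TraceSet, cells, window_ms: float = 5.0,
                    t_min_ms: float = 0.0) -> float:
    """Fraction of spikes with a partner spike within +/- window in every
    other listed cell (pairwise average); a crude synchrony index."""
    spikes = {c: traces.spike_times_ms(c) for c in cells}
    spikes = {c: s[s >= t_min_ms] for c, s in spikes.items()}
    fracs = []
    for a in cells:
        for b in cells:
            if a >= b:
                continue
            sa, sb = spikes[a], spikes[b]
            if sa.size == 0 or sb.size == 0:
                fracs.append(0.0)
                continue
            hit = np.mean([np.min(np.abs(sb - t)) <= window_ms for t in sa])
            fracs.append(float(hit))
    return float(np.mean(fracs)) if fracs else np.nan
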