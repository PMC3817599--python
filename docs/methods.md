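# Methods

This note documents the model equations, the numerical scheme, the
parameter choices that matter, and the limits of what the simulator shows.

## Units

The internal convention is the standard Hodgkin–Huxley system: voltage mV
(absolute; the resting reference is −60 mV), time ms, conductance density
mS/cm², absolute conductance mS, capacitance µF, current µA internally and
nA/nS at the public surface wherever parameters are commonly quoted that
way.  Lengths and diameters are µm, axial resistivity Ω·cm, extracellular
resistivity Ω·cm.  Astrocytic concentrations are µM internally (thresholds
are stated in nM at the API), with rate constants per second.

## Neurons

Both cell types are compartmental cables with the Traub-family channel
set.  Rate functions are written on the rest-relative voltage u = V + 60
(all published on that convention); reversal potentials are E_Na = +55,
E_Ca = +80, E_K = −75, E_leak = −60 mV absolute.  Gates: Na m²h; Ca s²
(high-threshold, activation only — the slow inactivation gate of the
original model is omitted because its constants are not recoverable and
burst generation in this family rests on s, χ, K_C and K_AHP); K_DR n;
K_A a·b; K_C c·min(χ/250, 1); K_AHP q with α_q = min(2·10⁻⁵ χ, 0.01).

Each compartment carries a dimensionless Ca pool
dχ/dt = −φ·I_Ca − χ/τ_χ (I_Ca as a density in µA/cm²).  φ and τ_χ are
per-compartment because the somatic and dendritic pools of the parent
models differ; the CA3 dendritic pools use φ = 0.08, τ_χ = 80 ms so that
one burst loads enough χ to pace the inter-burst silence.

**K_AHP deactivation.**  The backward rate of the q gate is a model
parameter, β_q = 0.0026 /ms (a ≈ 385 ms sAHP decay, inside the
physiological sAHP range).  With the literature value 0.001 /ms the
exponential q tail pins the inter-burst silence near 3 s for every channel
distribution we explored, which is incompatible with the observed ~0.66 Hz
burst rhythm at ~100 Hz intraburst frequency; β_q is therefore treated as
a calibrated constant and exposed in `gliosim.channels`.

**CA3 (21 compartments, branching).**  Equivalent-cylinder geometry: soma
125 × 42 µm; six basal and four apical-trunk compartments of 110 × 12 µm;
two apical branches of five 110 × 8.5 µm compartments.  Densities
(mS/cm²): soma Na 44, K_DR 17, K_A 5; proximal dendrites Na 12, K_DR 5,
Ca 5, K_C 10; mid dendrites Ca 10, K_C 10; distal Ca 4, K_C 5; K_AHP 1.8
and leak 0.1 everywhere dendritic.  Under the standard 0.6 nA somatic
drive the cell fires bursts of full-height action potentials at ~104 Hz
intraburst frequency repeating at ~0.69 Hz: the somatic Na/K_DR system
rides the dendritic Ca plateau; χ-activated K_C terminates the plateau and
the slow K_AHP paces the silence.  The per-compartment density tables of
the source models live in an unavailable supplement, so these layouts are
the package's own calibration with the burst signature as the anchor.

**CA1 (23 compartments).**  19-compartment backbone (soma, 8 basal, 10
apical; original numbering 1–19 with the soma at 9) plus axon initial
segment, axon proper, and two spine heads attached at the original 6th
(mid-basal) and 12th (proximal apical) compartments through an explicit
40 MΩ spine-neck resistance.  The CA1 cell is a regular responder: active
soma (Na 28, K_DR 16, K_A 5), hot IS/axon, and passive dendrites.
Dendritic Ca channels are deliberately absent — a dendritic Ca window
current makes the dendrite bistable, and a single strong SIC then latches
the whole network into a permanently active state.

The CA3 cell has no separate axon compartment (the published morphology
is 21 compartments of soma and dendrites), so its somatic voltage serves
both as the release-site voltage of the glutamate sigmoid and as the
spike-detection trace.

## Synapses

Cleft glutamate follows the release sigmoid with g_max = 3.5 mM,
V_p = 72 mV above rest, K_p = 5 mV, evaluated on the presynaptic axonal
(CA1) or somatic (CA3) voltage.  Receptors use first-order
transmitter-binding kinetics (AMPA α = 1.1 /mM/ms, β = 0.19 /ms; NMDA
α = 0.072 /mM/ms, β = 0.0066 /ms) with the conventional sigmoidal Mg²⁺
unblock on NMDA (1 mM Mg²⁺, γ = 0.062 /mV, K = 3.57 mM).  Anatomical
multiplicity (25 Schaffer contacts, 20 chain contacts) scales one kinetic
instance linearly; the model is deterministic, so duplicate state would be
identical anyway.  Per-contact peak conductances are calibration
parameters: 1.0 nS AMPA / 0.6 nS NMDA at the Schaffer synapse (sets the
lead cell's response rate) and 0.8 / 0.28 nS on the chain, which places
the chain at unity gain — smaller values let activity die along the pack,
larger ones make it run away, mirroring the "smallest numbers for
successful transduction" logic of the original wiring.

## SIC and gliotransmitter release

The SIC is implemented exactly in its printed form, I_SIC = scale ·
g_NR2B · h · v_s, with g_NR2B = 0.6 nS, no Mg²⁺ block and the driving
force equal to the absolute spine potential (a conventional v_s − E_rev
form and a clamp of h at 1 exist behind config flags, both default off).
The gate obeys dh/dt = σ/τ₁ − h/τ₂ (τ₁ = 92.3 ms, τ₂ = 568.5 ms).  Note
the fixed point σ·τ₂/τ₁ ≈ 2.46 exceeds 1 for sustained σ = 0.4; h is a
gating *variable*, not a probability, and is integrated as printed.

σ is the product of the hard release gate (0.4 iff Ca²⁺ > 200 nM,
strictly) and a deterministic exocytosis machinery: a docked-vesicle pool
drains with τ = 30 ms while release is ongoing and recovers with
τ = 1.8 s otherwise, with on/off hysteresis at 0.9/0.2 of the pool.  This
yields ~50 ms σ pulses (peak h ≈ 0.2) and exactly two release episodes
within one suprathreshold Ca²⁺ epoch of the default scenario — the
functional consequence of the Ca-dependent exocytosis model it stands in
for.  Each delivery site pools 3 eNMDAR units (`enmdar_sites`); at the
normal conductance the SIC gently recruits and synchronises the CA1 pack,
and at doubled conductance (epileptiform scenario) each release triggers a
high-frequency discharge lasting ≈ 0.6 s, the lifetime of the SIC itself.
SICs target the apical spine of CA1 1 and the basal shaft (original 6th
compartment) of CA1 2–4.

## Astrocyte

Two-variable Li–Rinzel ER dynamics (channel, leak and SERCA fluxes; slow
Ca-dependent IP₃-receptor inactivation w) with the standard constants
(v₁ = 6 /s, v₂ = 0.11 /s, v₃ = 0.9 µM/s, k₃ = 0.1 µM, d₁ = 0.13,
d₂ = 1.049, d₃ = 0.9434, d₅ = 0.08234 µM, a₂ = 0.2 /µM/s, c₀ = 2 µM,
c₁ = 0.185).  IP₃ relaxes to 0.16 µM with τ = 14 s and is produced from
sensed cleft glutamate through a saturating term (gain 19 µM/s,
K = 0.3 mM).  The gain is the calibrated constant anchored to the
observation that Ca²⁺ oscillations begin after ~10 s of CA3 activity: the
cleft glutamate is pulsatile with a sub-percent duty cycle, hence the
numerically large gain.  With the defaults the first 200 nM crossing
occurs at 10.6 s and suprathreshold epochs recur every ~12 s.  In clamp
mode Ca²⁺ is held at 100 nM (below threshold), all astrocytic derivatives
vanish, σ ≡ 0, and the CA1 traces are bit-identical to the
astrocyte-free network — the gliotransmission-incapacitated control.

## Numerical scheme

The production integrator is a fixed-step backward-difference method: per
step, gating variables advance by exponential (exact linear) updates from
voltage-indexed lookup tables (0.01 mV grid, linear interpolation), then
the voltage system — ionic conductances linearised about the updated
gates, synaptic and SIC conductances folded in — is solved implicitly
(backward Euler) on the compartment tree by Hines elimination.  Receptor
states and the SIC gate use closed-form linear updates; the astrocyte
states advance explicitly at the same step.  Default dt = 25 µs, recording
grid 0.5 ms.  The scheme is cross-checked against `scipy.solve_ivp` (BDF,
rtol 1e-8) on single-cell fixtures, and halving dt moves CA3 spike times
by well under 1 ms.  Runs are deterministic to machine precision.

Initial conditions: each cell at its channel steady state (found by
settling the zero-input dynamics for 20 s and polishing with a Newton
solve — Newton alone can land on a spurious depolarised Na-window
equilibrium), the astrocyte at its basal point, and a 0.5 s settle
interval before the stimulus that is excluded from analysis.  The full
network carries ≈ 1150 state variables, logged at assembly.

## LFP and analysis

CA1 compartment positions are laid out along straight somato-dendritic
axes (apical +y, basal −y) perpendicular to the cell row (x), somata at
x = 0, 25, 50, 75 µm and the electrode at (100, 0, 0) µm.  Transmembrane
currents are recovered exactly from the voltage traces through the axial
conductances (Kirchhoff), so per-cell currents sum to the injected current
at every sample.  IS and axon compartments are excluded (myelination);
resistivities are 643 Ω·cm at somata and proximal apical dendrites
(path distance ≤ 360 µm), 287 Ω·cm distal apical, 260 Ω·cm basal.  The
default source model is the line-source kernel; the point-source form is
used by the closed-form unit tests (1 nA at 25 µm in 643 Ω·cm →
20.5 µV).

Spectra are magnitude-squared FFTs of the complete analysis window
(periodogram; Welch averaging optional), peak frequency the argmax over a
configurable band (default 0.25–50 Hz), delta band 0.5–4 Hz.  Burst
metrics segment event trains at a 100 ms inter-event gap; intraburst
frequency is (spikes−1)/span averaged over multi-spike bursts and the
repetition rate is the reciprocal mean inter-onset interval.
High-frequency LFP episodes are segmented on the smoothed rectified
high-passed (10 Hz) envelope at 10% of each episode's own peak.

## Problem sizes

The shipped experiments are desk-scale by design: 5–10 s for the isolated
CA3 burst signature, 15 s for the astrocytic onset, 18–20 s for the
network scenarios (the first astrocytic epoch spans ~10.6–15.2 s, so a
12–18 s window holds one full release epoch).  The full 50 s horizon of
the original study remains a single config field.

## Known limitations

* The astrocyte-free LFP spectrum of this reconstruction peaks at the CA3
  burst-repetition fundamental (~0.7 Hz), not inside a 4–11 Hz mid-band
  envelope.  In this channel family the CA1 cells cannot fire sustained
  4–11 Hz trains between CA3 bursts: sub-threshold NMDA drive is largely
  Mg²⁺-blocked, AMPA drive exists only during presynaptic glutamate
  pulses, and the cells' f–I curves start near 15 Hz.  Consequently the
  gliotransmission-induced spectral shift appears here as increased
  synchrony, increased absolute delta-band power and slow SIC-locked
  envelope power — not as a strict downward shift of the spectral peak.
* The tripartite synapse is deterministic throughout: no stochastic
  vesicle release, channel noise, or background synaptic bombardment.
  Real LFPs ride on broadband background activity that this five-neuron
  pack cannot produce.
* Single astrocyte, point (non-spatial) Ca²⁺ dynamics, no gap junctions,
  no short-term plasticity, no receptor desensitisation beyond the
  first-order binding scheme.
* The per-compartment channel tables are calibrated against printed
  summary statistics (burst signature, Ca²⁺ onset, episode duration), not
  against the unavailable supplementary tables; absolute spike timing may
  differ from the original implementation even where the summary
  statistics agree.
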