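# Methods

## The model

`rgcsim` implements conductance-based multicompartment models of alpha-like
retinal ganglion cells (RGCs). A cell is a rooted tree of cylindrical
compartments — an equivalent-cylinder soma, a branching dendritic tree, and a
standardized four-region axon — each carrying nine Hodgkin–Huxley-type
currents. The membrane equation per compartment is

    C_m dV/dt = −[ g_L (V−V_L) + g_Na m³h (V−V_Na) + g_Ca c³ (V−V_Ca(t))
                 + (g_K n⁴ + g_K,A a³h_A + g_K(Ca)) (V−V_K)
                 + g_h l (V−V_h) + g_T m_T³ h_T (V−V_T)
                 + g_NaP p (V−V_Na) ] + I_axial + I_stim ,

with ionic currents positive outward (the standard Fohlmeister–Miller sign
convention). The delayed-rectifier, A-type, fast Na, HVA Ca, K(Ca) and leak
currents have fixed regional densities; the persistent Na (g_NaP), T-type
low-voltage-activated Ca (g_T), and hyperpolarization-activated (g_h)
maximal conductances form the free triple explored by the tuning machinery.

Gates obey first-order kinetics dx/dt = α(1−x) − βx, except the T-current
inactivation, a three-state scheme (available h_T, two closed states with
occupancy d and 1−h_T−d) advanced as a linear 2×2 system. The HVA Ca current
feeds a 0.1-µm sub-membrane calcium shell,
dCa/dt = −3 I_Ca/(2Fr) − (Ca−Ca_res)/τ_Ca, which sets both the dynamic Ca
Nernst potential (z = 2, 32 °C) and the K(Ca) conductance through a Hill
function of order 2 with dissociation constant 1 µM. The T current uses the
fixed reversal +120 mV; only the HVA current drives the shell. The factor 3
in the shell source term is retained exactly as the model defines it.

Two kinetic expressions circulate in more than one form and required a
choice. For the T-activation closing rate we use the Wang-lineage form
β_mT = exp(−(V+63)/7.8) / (1.7 + exp(−(V+28.8)/13.5)), i.e.
m∞ = 1/(1+exp(−(V+63)/7.8)), the T-current model this cell model is built
on; the variant with a leading "1 +" in the numerator caps m∞ at ½, weakens
I_T eightfold after cubing, and eliminates the rebound-oscillation regime
entirely. For the NaP gate the opening rate is α_p = p∞/τ_p with
p∞ = 1/(1+exp(−(V+48)/10)) and the piecewise τ_p (continuous at −40 mV;
both branches give 0.165 ms there) — the only combination in which both
rates carry units of 1/ms. No temperature (Q10) scaling is applied to any
rate; temperature enters only the Nernst relation.

## Geometry and channel layout

The axon is identical for every cell: a 40-µm initial segment (diameter
equal to the distal axon's 1 µm), a 90-µm narrow segment (0.4 µm), and a
5340-µm distal axon. The sodium-channel band (SOCB) is an overlay on the
arc interval [30, 70) µm — the distal 10 µm of the initial segment plus the
proximal 30 µm of the narrow segment — carrying 5× the somatic Na and NaP
densities and no K, K,A, Ca or K(Ca) channels. Membership is decided by the
compartment midpoint's arc distance, and the discretizer pins compartment
boundaries at 30, 40, 70 and 130 µm so the band is exactly representable at
any resolution. The distal axon carries 1/20 of the somatic NaP density
(required for orthodromic propagation) and a 25× leak; everywhere else the
leak is 15 × 8·10⁻⁶ = 1.2·10⁻⁴ S/cm², the adjustment that compensates for
the three added inward currents. Dendrites carry 5× the nominal g_T; g_h is
uniform in all regions. The printed distal-axon K(Ca) ceiling of
0.07 S/cm² is retained as the default (exposed as an override because it is
suspiciously large — three orders above the somatic value); its measured
consequence is slow distal-axon conduction (~15 ms soma-to-terminal) with
initiation order unaffected.

Surface areas are lateral cylinder areas without end faces, and the "total"
area of a cell excludes the axon, which is shared by construction
(π·5416 ≈ 17 015 µm²). Soma reconstructions are collapsed to a single
cylinder of equal lateral area with aspect ratio L = d (a lone SWC soma
sphere of radius r becomes d = L = 2r). Coordinates are used only to derive
cylinder lengths; the electrical model is purely topological.

## Numerics

Integration is operator-split per step: (1) exact exponential update of
every first-order gate at frozen voltage; (2) one implicit step of the
(h_T, d) pair; (3) exact update of the calcium shell at the frozen Ca
current; (4) an implicit (backward Euler) solve of the voltage system with
ionic conductances frozen at the new gating values. The voltage solve is a
Hines elimination on the compartment tree — one O(N) backward sweep and one
O(N) forward sweep over a parent-before-child ordering — which is
unconditionally stable for the stiff SOCB densities (g_Na = 0.4 S/cm²). A
Crank–Nicolson variant (half-step solve plus extrapolation of the linear
part) is available; backward Euler is the default. The inner loop is
compiled with numba.

Defaults: dt = 0.025 ms, maximum compartment length 40 µm (well under the
dendritic length constant of ~400 µm), axial resistivity 110 Ω·cm (not
specified by the model; the Fohlmeister–Miller lineage value, exposed in the
config), initialization at −65 mV with gates at steady state and calcium at
the residual level, and 500 ms of settling before any measurement window.
Removable singularities in the opening rates (at −30, −13, −40, −90 mV) use
a second-order series within 10⁻⁶ mV of the singular point. The calcium
shell is floored at 10⁻¹² M so the Nernst potential stays defined under
outward Ca current. Convergence was checked by halving dt and the segment
length: rebound latency, resting and hyperpolarized potentials move by
< 0.2 ms / < 0.1 mV.

## Measurements

Spikes are upward crossings of 0 mV (first suprathreshold sample, 1 ms
refractory); only overshooting action potentials are counted anywhere in
the package. Resting potentials are spike-removed means: samples within
2 ms after any point where dV/dt exceeds 10 mV/ms are excised and the rest
averaged over at least 1 s (a flag marks shorter windows). The CV of the
interspike interval uses the sample (n−1) standard deviation (the
convention is not specified upstream; noted here). Oscillation analysis
de-spikes by interpolation, detrends, and takes a Welch periodogram (4-s
windows, 0.25-Hz bins); presence requires a 0.5–12 Hz peak with ≥ 3× the
median spectral power and a band-passed peak-to-peak of ≥ 0.1 mV (noise
floor; real oscillations are 0.5–10 mV), and "sustained" means the final
half of the window retains ≥ 50 % of the first half's amplitude. Sag is the
depth of the early minimum (first 200 ms of a step) below the steady level
(mean of the last 20 % of the step), reported as a non-negative magnitude.
Rebound burst rate counts spikes in the 200 ms after step offset; the
latent period is offset-to-first-rebound-spike.

Input resistance is ΔV/ΔI from somatic steps using spike-removed means
(baseline vs probe windows of 1 s). On quiescent cells a −20 pA probe is
used; on spontaneously firing cells the small-signal probe is swamped by the
limit cycle, so the leak-sweep experiment probes with the −0.2 nA step — the
companion protocol of the published sweep. A secondary mode averages ΔV/ΔI
at the first compartment of each primary dendrite.

## Phenotype constraints and search

C0: action potentials must overshoot 0 mV — a cell fails when it produces
spike-like events (peaks above −40 mV with ≥ 20 mV prominence) none of
which reaches 0 mV; decaying late-burst spikelets do not fail an otherwise
overshooting cell. C1: rest in [−70, −62] mV (ON) or [−62, −50] mV (OFF).
C2: spontaneous rate 0 (ON), 15–23 Hz (OFF transient), 40–48 Hz (OFF
sustained). C3: no spikes during the −0.2 nA / 500 ms step. C4: zero
rebound (ON) or rebound rate ≥ 2× the spontaneous rate (OFF); an OFF cell
with zero spontaneous rate cannot satisfy the relative rule and is labelled
none. The three phenotype predicates are mutually exclusive by
construction. Grid search evaluates a lattice of triples (coarse decade
steps over [10⁻¹⁵, 10⁻¹] S/cm² by default, with a linear refinement pass
over the bounding box of labelled points); results are cached by triple and
independent of evaluation order. Valid sets are connected components under
6-neighbor face adjacency (the strictest reading of "connected"; 26-neighbor
is a flag), with singletons flagged separately. The staircase validation
classifies per-level regimes as silent (no spikes), regular (CV < 0.3),
irregular (CV ≥ 0.3), or burst (irregular with ≥ half the ISIs under 20 ms
while the spikes span < half the window) — the burst/regular thresholds are
package definitions of a qualitative description.

## The synthetic morphology generator

No reconstruction files ship with the package; the generator emulates the
published population's aggregate morphometry only. Cells are a soma plus
regular binary trees: each of n primary dendrites bifurcates `branch_depth`
times, segment lengths are truncated-normal, and diameters taper by a fixed
ratio per branch order. The `compliant` preset (soma 16.3 µm, 4 primaries,
depth 2, lengths 55 ± 12 µm, taper 0.7) targets the constraint-meeting
population means (total area ≈ 5230 µm², dendrite ratio ≈ 0.84); the
`noncompliant` preset (soma 12 µm, 3 primaries, depth 4, uniform 1-µm
dendrites) targets the non-meeting means (≈ 14 000 µm², ≈ 0.97). Generation
is a pure function of the seed; each cell draws from its own RNG stream,
and regeneration reproduces the checked-in reference SWC byte for byte. The
reference cell is the compliant preset at seed 1 (total area 5315 µm²,
dendrite ratio 0.843, 16 tips, R_in = 169 MΩ at the adjusted leak).

What the generator does not emulate: dendritic-field planarity,
stratification, Sholl profiles, realistic topology variation, or any
per-cell correspondence to a real reconstruction. Passing tests therefore
demonstrate that the dynamics and measurements behave as published for a
cell drawn from the published morphometric ranges — not that any particular
real cell is reproduced. Quantities that depend on where a particular cell
sits inside the population (its input resistance, hence the current needed
to silence it, the depth reached under a fixed current step, rebound
latency) inherit that spread; the reference cell sits at the population
mean of the constraint-meeting group and behaves accordingly (deflection of
34 mV under −0.2 nA at R_in 169 MΩ; tonic firing still present at −0.06 nA
with slow burst-oscillations at −0.08 to −0.12 nA and silence at −0.14 nA).

## Problem sizes

Desk-scale throughout, chosen as the package's own working defaults: the
reference cell compiles to 193 compartments; single-cell protocols run 1.5
to 17 s of biological time; the bundled conductance search covers a few
dozen lattice points rather than the cluster-scale full grid; population
statements about the generator use 50 seeds per preset.

## Known limitations

Synaptic input, extracellular stimulation, Na-channel subtypes, stochastic
gating and multi-cell circuits are out of scope. The distal-axon K(Ca)
density is kept as published although it slows distal conduction (override
available). The dendritic input-resistance mode implements an ambiguous
verbal definition and is secondary. The staircase regime thresholds and the
oscillation presence criteria are package choices calibrated only against
synthetic signals with known content.
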