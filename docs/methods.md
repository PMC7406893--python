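# Methods

This note records the physical models, numerical schemes, calibrated
parameters and known limitations of the package. Units: SI internally;
reported fields in mV/m, magnetic fields in nT, current densities in mA/m²,
charge densities in C/m³, following the NV-sensing literature.

## Membrane action potential (`neuropillar.hh`)

The membrane is the classic squid-axon conductance model — Na, K and leak
channels with gating variables m, h, n — with every voltage rigidly shifted
so the resting potential is −68 mV, appropriate for a mammalian neurite.
Defaults: C_m = 1.0 µF/cm², g_Na = 1200, g_K = 360, g_L = 3 S/m², reversal
offsets +115/−12/+10.613 mV from rest (the classic values, which make rest an
equilibrium). Integration is fixed-step RK4 (4th order) at dt = 0.005 ms; the
fastest gating time constant at these kinetics is ~0.1 ms, so the step is
resolved by more than an order of magnitude. The suite cross-checks the
trajectory against an adaptive high-accuracy integration of an independently
coded right-hand side.

**Temperature.** A Q10 = 3 rate-scaling machinery is provided, referenced to
the model's original 6.3 °C calibration, but the default applies no scaling.
Scaling the kinetics to 37 °C speeds gating ~29×, which drives the upstroke
rate (and hence the axial current and every downstream field magnitude) an
order of magnitude above the values this package is calibrated to reproduce;
the unscaled kinetics give an upstroke of ≈320 V/s, which is what the field
calibration below assumes. The bath temperature used for electrodiffusion
thermodynamics is 310 K regardless.

**Stimulus handling in the traveling wave.** The default stimulus is a
1 A/m², 0.3 ms pulse; the AP then develops freely. When the trajectory is
frozen into the co-moving frame (ξ = −v(t − t_peak), wave moving in +z, peak
at ξ = 0), the stimulus term is removed from dV/dt: a steadily propagating AP
is stimulus-free, and keeping the pulse's square edges would freeze ±100 V/s
discontinuities into the axial-current profile, which propagate into
unphysical kinks of the membrane charge and spurious A/m²-scale exterior
currents.

**Axial current.** I(ξ) = (π a² / ρᵢ v) dV/dt with a = 500 nm,
ρᵢ = 1 Ω·m. With the defaults |I| peaks at ≈1.47 nA.

**Calibration of v.** The conduction velocity is a free parameter of the
frozen-wave construction. Two closed-form relations tie it to the target
field magnitudes: the peak membrane charge is σ_pk = C_σ V_rest + I_pk/(2π a v)
with I_pk ∝ 1/v, and B_pk = µ0 I_pk/(2π a). v = 0.17 m/s places the peak
membrane field at ≈3.3×10⁹ mV/m and B at ≈0.6 nT simultaneously; it is a
calibrated, not measured, value.

## Exterior electrodiffusion (`neuropillar.pnp`)

Steady co-moving Poisson–Nernst–Planck on the annulus a ≤ r ≤ R_max
(R_max = 3 µm), |ξ| ≤ 3 mm, for two effective monovalent species: the grouped
cations (Na⁺, K⁺; D = 1.645×10⁻⁹ m²/s) and grouped anions (Cl⁻ and organic
anions; D = 1.265×10⁻⁹ m²/s), both at 150 mol/m³ bulk, ε = 80, T = 310 K.
The frame substitution ∂/∂t → −v ∂/∂ξ adds a −v c advective flux along ξ.

**Membrane boundary data.** The axon interior enters only through boundary
conditions at r = a:

* Gauss's law gives a Neumann condition ε ε0 ∂V/∂r = −σ(ξ) with
  σ(ξ) = C_σ V_rest + I(ξ)/(2π a v): the resting capacitor charge plus the
  co-moving line charge λ = I/v (traveling-wave charge continuity,
  −v λ′ = −I′) spread over the circumference.
* The rest-referenced channel currents become molar fluxes: Na and K on the
  effective cation, leak on the effective anion, each divided by (z F).
  Rest-referencing makes the resting state a true equilibrium double layer.

The charge-coupling capacitance C_σ = 0.52 µF/cm² is a second calibrated
constant, distinct from the dynamical C_m: it sets the resting membrane field
σ_rest/(ε ε0) to ≈−0.5×10⁹ mV/m. (The dynamical value, 1.0 µF/cm², would put
it at −0.96×10⁹.) Both calibrated values are printed into every run manifest.

**Discretization.** Cell-centered finite volumes on a tensor mesh:
geometrically graded radial cells starting at 0.15 nm (≤ λ_D/5;
λ_D ≈ 0.81 nm at 150 mol/m³, 310 K) growing to the outer radius in 250
cells, and 400 uniform axial cells (15 µm). The mesh builder refuses first
cells above λ_D/2. Face fluxes are Scharfetter–Gummel exponentials with the
frame advection folded into the axial drift Peclet number; this is exact for
locally exponential (Boltzmann) profiles, which is what makes the sub-nm
double layer representable on ~16 cells. Boundaries: bulk Dirichlet at
R_max, prescribed-flux at the membrane, advective outflow (zero-gradient) at
the trailing ξ end and bulk inflow at the leading end.

The 6-mm axial extent is set by the after-hyperpolarization: at v = 0.17 m/s
the membrane needs ≈17 ms ≈ 2.9 mm of trailing room to relax within ~0.3 mV
of rest, and the frozen-wave construction requires rest values at both ends.

**Solver.** The coupled system is solved by a fully coupled damped Newton
iteration on the stacked unknowns (V, c₊, c₋): Poisson rows couple to the
concentrations through the charge density, transport rows couple back to V
through the drift dependence of the Scharfetter–Gummel fluxes (assembled
analytically via B′(x)). A segregated Gummel sweep was measured to contract
at only ~0.95–0.97 per iteration here — the electrolyte's screening response
has near-unity loop gain on a domain thousands of Debye lengths wide — while
the coupled Newton converges in 3 iterations to a 10⁻⁸ relative residual
(scaled by the Gauss-law boundary term and the peak membrane flux
respectively). The Jacobian factorization is reused across iterations
(modified Newton) since the nonlinearity is ~1% at these mV-scale surface
potentials; steps that would drive a concentration negative are damped. The
initial iterate is the linearized Debye–Hückel screened solution with
Boltzmann concentrations.

**Validation.** At v = 0 with the resting charge the solve reproduces the
planar Gouy–Chapman closed form within 0.2% (curvature correction λ_D/a
≈ 0.2%); the far field is neutral and grounded. Discrete species
conservation is verified per cell against the cell's gross flux turnover
(satisfied at ~10⁻¹²; note that normalizing the net flux by the *membrane*
flux alone is not resolvable in double precision — the screening-layer face
fluxes whose cancellation defines the net flux are ~10⁷ times larger,
leaving a rounding floor near 4×10⁻⁷ of that scale).

## Field maps and comparator (`neuropillar.fields`)

E = −∇V by second-order centered differences on the graded mesh (the
membrane-line value is reported from the Gauss-law boundary term, which is
exact on the discrete level); ρ = F(c₊ − c₋); j from the drift–diffusion
flux. B_φ comes from the integral form of Ampère's law: the internal axial
current I(ξ) plus the exterior axial current integrated over the annulus by
cumulative trapezoid. The core-conductor comparator implements the canonical
micron-scale description — the line-source extracellular potential
V_e = (1/4πσ_e) ∫ i_m(ξ′)/√(r² + (ξ−ξ′)²) dξ′ with i_m = −dI/dξ, and the
wire field µ0 I/(2π r) — with σ_e = 1.5 S/m by default; it is a canonical
comparator, not a line-by-line reproduction of any published variant. The
1/r fit is linear least squares for the amplitude A of A/r with a relative
RMS residual.

With the calibrated defaults the solve gives: peak membrane field
+3.3×10⁹ mV/m, resting field −0.5×10⁹ mV/m, peak membrane B 0.57 nT, the
AP-induced field change screened below 5% within 2.6 nm, charge-density
extremes ≈−2.6×10⁶ and +1.1×10⁶ C/m³, and a peak exterior axial current
density ≈0.8 A/m². The last figure deserves a comment: it is the
volume-conductor return current of the membrane current per length
i_m ≈ 5×10⁻⁵ A/m, and scaling analysis (j_ξ ∝ 1/v³ at fixed kinetics,
while the peak E pins I/v and B pins I) shows it cannot be made an order of
magnitude smaller without abandoning the field and B calibrations; it is
reported as computed.

## Pillar Laplace solutions (`neuropillar.pillar`)

Good contact removes the screening ions over the contact patch, so the
unscreened membrane normal field E0 (taken from the electrodiffusion peak)
drives the pillar interior; the Debye layer pins V = 0 on the rest of the
wetted diamond surface. No dielectric-contrast amplification is applied by
default (an optional factor exposes it); a Dirichlet-contact variant is
available behind `dirichlet_value`.

**On-top** (neurite across the full top disc, diameter d = 200 nm):
separable series V = Σ A_n J0(j_{0n} 2r/d) exp(−j_{0n} 2z/d) with
A_n = E0 d/(j_{0n}² J1(j_{0n})) from the uniform normal-field condition;
200 modes by default (the z ≥ 1 nm evaluations used here are converged to
<10⁻³). The slowest mode decays at 2 j_{01}/d = 4.8097/d. The series is
verified against an independent axisymmetric finite-difference solve (2%).

**On-side** (square patch of area π d²/4, side 177 nm, wrapped on the
lateral wall with its upper edge at the tip): cell-centered finite-volume
Laplace in cylindrical coordinates; the axis needs no boundary condition
(zero face area), patch faces carry the Neumann drive with partial faces
area-weighted, and the system (SPD) is solved by Jacobi-preconditioned
conjugate gradients to 10⁻⁸. Default grid 40×96×140 (≈0.5M cells, seconds on
one CPU); refinement to 56×136×200 moves the reported field by ~2.5%.

The top disc is flux-free by default in the on-side geometry rather than
grounded: a neurite of ≈500 nm radius contacting the side of a 100-nm-radius
pillar necessarily overhangs the tip and displaces the screening layer there
as well. This choice matters — grounding the top short-circuits ~25% of the
axis field — and the flux-free reading reproduces the on-side magnitude the
package is calibrated against; `grounded_top=True` restores the fully grounded variant.

## NV detectability (`neuropillar.nv`)

Minimum detectable field = S/(η √t_acq) with published DC sensitivities
S_E = 891 V cm⁻¹ Hz^(−1/2), S_B = 40 nT Hz^(−1/2), t_acq = 1 ms (the peak
neuronal signal duration) and collection enhancement η (1 bulk, ~5 pillar).
Unit conversions are centralized (V/cm → mV/m is ×10⁵); values are rounded
only at presentation. Note the unrounded η = 5 magnetic threshold is
253.0 nT while the commonly printed value (252 nT) comes from dividing the
already-rounded 1.26 µT; the report footnote flags that published margin
claims for the on-side electric channel differ by an order of magnitude
between sources, so margins near unity are qualitative.

## Growth imaging (`neuropillar.growth`)

Pipeline: global Otsu (or fixed) threshold → connected-component cleanup
(min 30 px) → topology-preserving thinning → decomposition of the 8-connected
skeleton graph into simple paths at branch points. The ordering metric
resamples each path at 8-px chords (removing the 45° step quantization of
raw skeletons), drops paths under 6 px (junction debris), and classifies a
segment as *ordered* when its orientation is within θ_tol = 10° of either
grid axis (the tolerance is not fixed by prior art; it is exposed in config
and printed in outputs). Ordered fraction = ordered length / total length,
reported as missing (not 0) for empty images. Total growth is the foreground
area fraction — skeletons discard thickness and are unsuitable for it.

**Synthetic generator.** Persistent random walks (heading jitter 1.5°/step
with a restoring pull toward the base direction), a dialled fraction locked
to the row/column axes, the rest on oblique base directions drawn from
20–70° off-axis so the ground-truth label is unambiguous at the default
tolerance; walks terminate at the field edge (clipping would fabricate
axis-aligned border runs). Rendering: 3-px dilation, σ = 1 px Gaussian blur,
5% additive noise, 512² px at 0.2 µm/px; all randomness from one seed. The
generator emulates the geometry of stained neurites on a pillar grid, not
their photometry: no cell bodies, no astrocyte channel, no uneven
illumination, no pillar autofluorescence. Passing recovery tests therefore
demonstrates that the measurement chain is unbiased on images whose
difficulty is curvature, crossings and noise — not that it is robust to
every artifact of real micrographs. Isotropic orientations calibrate the
metric's floor at 4 θ_tol/180 ≈ 0.222; the dial is recovered with mean
absolute error < 0.07 across its range.

## Problem sizes and determinism

The default electrodiffusion mesh is 250×400 cells (the Newton solve
factorizes one ≈300k-unknown Jacobian and converges in 3 iterations); the
on-side pillar grid is 40×96×140 with a 28×64×100 Richardson companion.
These sizes hold every reported figure stable at the few-percent level. All
physics stages are deterministic (no RNG); the synthetic-image cohort is
driven by a single integer seed, and rerunning a configuration reproduces
byte-identical CSV outputs.

## Known limitations

* Exterior-only electrodiffusion: the axoplasm appears solely through the
  frozen HH boundary data; the pillar is absent from the electrodiffusion
  domain (the pillar stage assumes the unperturbed membrane field drives the
  contact patch), and membrane dielectric thickness is not resolved.
* The frozen traveling wave cannot describe AP initiation, collision, or
  dispersion; v is a calibration constant, not a cable-theory prediction.
* The effective two-species electrolyte cannot track species-specific
  concentration changes (e.g. K⁺ accumulation).
* The exterior axial current density the model produces is set by the return
  current of the calibrated waveform (~0.8 A/m² peak); see the field-maps
  section for why this figure is not independently adjustable.
* The growth metric's absolute value depends on θ_tol and on skeleton
  quality in dense cultures; cross-study comparisons should fix both.
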