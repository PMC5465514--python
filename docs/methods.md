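# Methods

This note records the models implemented by `cardioviz`, the numerical
choices behind them, and what the synthetic phantom does and does not
establish about real cardiac data.

## Cell model

The myocyte is the ten Tusscher & Panfilov (2006) human ventricular model
(TNNP06), transcribed from the published formulation (Am J Physiol Heart
Circ Physiol 291:H1088–H1100), including its endo-/mid-/epicardial
variants. The 19 state variables (V_m, 11 voltage gates, the
subspace-calcium gate f_Cass, the RyR adaptation variable R', and the
Ca_i/Ca_SR/Ca_SS/Na_i/K_i pools) and all 12 currents are exposed
individually (`cardioviz._tnnp06.ionic_currents`) so each current is
testable on its own. Units are mV, ms, mM and pA/pF; currents are
normalized per membrane capacitance, so C_m enters the voltage equation as
1 and the whole-cell capacitance (0.185 µF) appears only in the
concentration balances, as in the source model.

Right-ventricular epicardium scales I_Ks by 2 and I_to by 4, reflecting
the reported RV/LV density differences; the scaling touches only those two
conductances (asserted bit-exactly in the tests).

### Integration scheme

Hodgkin–Huxley gates use the Rush–Larsen update
n(t+Δt) = n_∞ − (n_∞ − n(t))·exp(−Δt/τ_n), which is the exact solution of
the gate ODE while rates are frozen over the step; f_Cass uses the same
exponential form with its Ca_SS-driven target. R', the five concentration
pools and V_m itself use forward Euler. The cell step is Δt = 0.02 ms.
The removable singularity of the GHK-type I_CaL driving term at
V_m = 15 mV is evaluated through the limit of z/(e^z − 1).

Two implementations exist deliberately: a vectorized numpy reference
(readable, returns every current) and a scalar numba kernel used by the
run loops; a test pins them together to ~1e-12 relative per step, so the
fast path cannot drift from the documented equations.

### Initial conditions

Packaged quiescent states per cell class are produced by
`scripts/make_rest_states.py`: a 40 s unstimulated relaxation at
Δt = 0.02 ms from the published paced steady-state values, frozen as
module constants. 40 s balances two requirements: the residual drift must
be below 0.01 mV per second of simulation (at 10 s it is still
~0.03 mV/s), while the unstimulated model keeps drifting slowly toward its
true unpaced equilibrium near −86.6 mV, which would leave the −86.0 ±
0.5 mV resting anchor. After 40 s the rest sits at −86.29 mV with
~0.007 mV/s residual drift; a further 5 s run ends at −86.33 mV. The
remaining few-tenths-mV gap to the −86.0 mV color-scale anchor is a
property of the cell model's slow Na⁺ balance, not of the integrator, and
is noted rather than tuned away; the color scale keeps the −86.0/+45.0
anchors regardless.

## Tissue model

Propagation is monodomain with a scalar diffusion coefficient
(default D_global = 0.154 mm²/ms, optionally expressed as K/(R_m·C_m)) on
a regular voxel lattice (default 0.33 mm isotropic). 0.154 mm²/ms is
treated as the (maximum) global value; an optional per-tissue-class
override table (`tissue.D_per_class` in the config) supplies a per-voxel
coefficient field, with the stability bound evaluated at the largest D in
use. Whether distinct tissue classes should receive distinct D is left to
the user; the default is the single scalar. No-flux boundaries on
the irregular tissue surface use a phase field φ: the flux is
D_global·φ·∇V_m, so wherever φ → 0 the normal current vanishes without any
explicit surface bookkeeping. φ is 1 inside tissue and 0 outside. (The
opposite orientation would multiply the reaction term by zero on tissue
and is not meaningful.)

### Phase-field construction

φ is relaxed once per geometry from the binary tissue mask under
∂φ/∂t = ξ²∇²φ − G'(φ) with the double well
G(φ) = −(2φ−1)²/2 + (2φ−1)⁴/4 (equal minima at 0 and 1) and ξ = 0.33 mm.
The pseudo-time step is a quarter of the diffusion-stability bound with ξ²
in place of D. Relaxation runs for a short pseudo-time (default 1.0),
long enough for the interface profile of width O(ξ) to form: the same
equation also moves interfaces with curvature, so relaxing to equilibrium
would erode and eventually delete wall-thin structures. Voxels with
φ < 0.01 are excluded from the dynamics entirely.

### Discretization

The divergence term uses face-centred fluxes with φ averaged
arithmetically onto faces and zeroed on faces touching an excluded voxel.
Summed over the lattice the fluxes telescope exactly, so with the reaction
off Σ(φ·V_m) is conserved to roundoff (~1e-16 relative per step) for
arbitrary masks — the discrete form of the no-flux condition, and the
property the acceptance suite checks at 1e-8 over 1000 steps. A
brute-force triple-loop oracle reproduces the vectorized operator
bit-exactly.

Time stepping is forward Euler under Δt ≤ Δς²/(2d·D_global); at the
defaults the bound is 0.118 ms and the solver runs at 0.02 ms, which also
covers the mild sharpening of the effective bound where φ varies across
the interface. The solver refuses a Δt above the bound. Non-tissue voxels
inside the smoothed interface carry V_m (they form a thin diffusive halo)
but no ionic state; the whole field starts at the resting potential.
Activation maps record the first upward crossing of −20 mV, a threshold
robustly above notch and plateau artifacts.

### Stimulation

Square current pulses over voxel regions; negative amplitude depolarizes
(I_stim enters as −(I_ion + I_stim)). The conventional pulse is −52 pA/pF
for 1–2 ms. S1–S2 is a conditioning pulse followed by one premature pulse
after a configurable coupling interval.

## Ventricle phantom

The phantom stands in for segmented cryosection data: a thick-walled LV
ellipsoidal shell and a thinner RV shell wrapped against it (RV yields to
the LV wall, guaranteeing a single 6-connected excitable component), both
open above a base plane, apex toward low z, inside a padded background
box. Gray labels (LV 40, RV 50) lie in the 30–70 band where cardiac
tissues live in converted cryosection stacks; the organ palette (LV cyan,
RV pale red, atria purple/tan, aorta yellow) is data, not code, and is
overridable for real volumes. A low-frequency radial jitter (2 % of the
radius, seeded) keeps the surface from being exactly quadric. Default
size 60 × 60 × 80 voxels at 0.33 mm runs the full pipeline in minutes.

What the phantom does not emulate: fiber orientation (and hence
anisotropic conduction), trabeculation, atria and vessels as excitable
structures, wall-thickness heterogeneity, and the gray-level noise of real
cryosections. Tests passing on the phantom therefore validate the
numerics and the ordering/conservation properties, not anatomical realism.

## Scaled-down re-entry demonstration

The full-organ re-entry of a human ventricle needs an excitation
wavelength (conduction velocity × APD ≈ 0.7 mm/ms × 300 ms ≈ 200 mm) far
larger than a desk-scale domain. The demo therefore shrinks the
wavelength, not just the grid: on a 100 × 100 slab (33 × 33 mm) it scales
g_Kr and g_Ks by 8 and g_CaL by 0.5 (APD90 ≈ 83 ms — the same conductance
family the restitution literature varies) and reduces coupling to
D = 0.04 mm²/ms (CV ≈ 0.33 mm/ms, wavelength ≈ 27 mm). A planar S1 at one
edge is followed by S2 over one quadrant; scanning coupling intervals in
steps of 10 ms found 120 ms as the first interval in the vulnerable
window, which is frozen as the demo default (100 and 110 ms give
propagation that dies with the S2 wave; 120-150 ms spawn a re-entrant
wave that outlives twice the APD after the stimulus). The persistence
criterion — activity beyond 2×APD90 after the S2 pulse — is the
operational definition of re-entry here.

## Rendering

Transfer lookups are piecewise linear with clamping. The potential scale
anchors −86.0 mV to blue and +45.0 mV to red with a
blue→cyan→green→yellow→red path (the hue path between the anchors is a
package choice; only the endpoints are normative). Anatomy and potential
scales are independent maps.

Per-sample merged opacity is τ′ = α_a·α_e·mef. Design choices:

- **mef.** A literally "normalized normal vector" has norm 1 and makes the
  branch vacuous; implemented as min(1, |∇V_a|/g95) with g95 the 95th
  percentile of the anatomy gradient magnitude, preserving the intent:
  where no potential data exists, only anatomical boundaries attenuate,
  producing the translucent-chamber effect.
- **No-data flag.** An in-band V_e = −1 sentinel collides with real
  membrane potentials crossing −1 mV during repolarization; a support mask
  marks "no EP data" instead (the sentinel is honoured only when importing
  third-party volumes using that convention).
- **Emission weights.** The blend uses one consistent opacity pair
  (α_e(x), α_a(x′)) in both weights, which then sum to 1 whenever
  α_e + α_a > 0.
- **Attenuation sign.** The optical depth attenuates (transmittance ≤ 1,
  monotone non-increasing along the ray).
- **Compositing.** τ′ is opacity per sample interval; the per-segment
  optical depth is −ln(1−τ′), making classic front-to-back compositing the
  exact solution of the attenuated-emission integral for piecewise-
  constant fields (the quadrature-agreement test), with early termination
  below 1e-4 transmittance. Rays are orthographic by default; both
  volumes are sampled trilinearly; the ray step must not exceed half the
  voxel spacing.
- **Degeneracy.** A fully transparent potential LUT disables the EP volume
  and reproduces the single-volume baseline renderer bit-exactly — the
  regression anchor tying the merged path to the classic light-transport
  model.

## Configuration and reproducibility

One YAML file with per-command sections; unknown keys are rejected;
configs round-trip unchanged and are content-hashed into each run's
`manifest.json` together with seeds, versions, the stability bound and the
Δt used. Problem sizes used by the test and acceptance runs (60 × 60 × 80
phantom, 100 × 100 slab, 5 s single-cell runs) are the package's default
desk-scale study conditions.

## Known limitations

Scalar isotropic diffusion (no fiber architecture); no bidomain effects;
forward Euler/Rush–Larsen only (no operator splitting or adaptive
stepping); the renderer has no shadows, perspective is not the default,
and color handling is linear RGB; the phantom's geometry is idealized; the
unstimulated rest potential sits ~0.3 mV below the −86.0 mV color anchor
(see Initial conditions).
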