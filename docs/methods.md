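# Methods

`emwedge` simulates a transmural block ("wedge") of human left-ventricular
wall as a strongly coupled electromechanical system, in a normal (NF) and a
failing (HF) parameterization, and measures how contraction feeds back on
repolarization: activation/repolarization times and their transmural
dispersions, wall thickening, and the transmural electrogram.

## Cell model

Membrane electrophysiology follows the ten Tusscher–Noble–Noble–Panfilov
(2004) human ventricular model with its endocardial, midmyocardial (M) and
epicardial variants (the variants differ in `g_to`, `g_Ks` and the
`s`-gate kinetics). The implementation reproduces the published 1 Hz
single-cell behaviour to a few percent: resting potential −86.2 mV,
diastolic/systolic Ca²⁺ ≈ 0.07/1.0 µM, Na_i ≈ 11.5 mM, APD₉₀ ordering
epi < endo < M. APD₉₀ values come out 3–5 % below the published ones
(268/272/318 ms vs 276/282/336 ms); the difference is independent of the
integrator step and we could not attribute it to any printed equation, so
it is carried as a known reimplementation bias. It matters downstream
because the minimum repolarization time of the wedge tracks the
endocardial APD directly.

Active force is generated by the Rice et al. (2008) mean-field crossbridge
model, driven one-way by the calcium transient (Ca_i is an input to the
troponin/crossbridge chain; no buffering feedback on Ca_i). The sarcomere
is isosarcometric at SL = 2.2 µm by default — mechano-electric feedback
other than the diffusion-tensor deformation is deliberately out of scope.
Crossbridge cycling rates carry the model's species modifier 0.2 (its
rabbit/human slow-cycling setting); without it the twitch saturates
(peak normalized force ≈ 0.9) and the NF/HF force contrast that drives the
wall-thickening difference disappears. Rate constants are used at 37 °C
(all Q₁₀ corrections equal one). The normalized force is
`T_a = SOVFThick (x_XBpostr XBpostr + x_XBprer XBprer) / (x₀ SS_XBpostr)`.

### Late sodium current and heart failure

HF remodeling has three parts:

1. **Late sodium current** `I_NaL = g_NaL m_L³ h_L (v − E_Na)` with the
   Ebihara–Johnson/Luo–Rudy `m`-gate rates
   (`α_mL = 0.32(v+47.13)/(1−e^{−0.1(v+47.13)})`, removable singularity
   handled by its limit 3.2 ms⁻¹), `h_L∞ = 1/(1+e^{(v+91)/6.1})`,
   `τ_hL = 233 ms`. The nonfailing cell carries no I_NaL; the failing cell
   uses 3 × a reference conductance g₀ = 0.03 nS/pF. g₀ is a free
   parameter of the formulation (published HF variants span roughly
   0.0065–0.02 nS/pF and beyond); it was chosen once, within that spread,
   so that the remodelled cells reproduce the qualitative HF phenotype
   (APD prolongation in all three types and the transmural APD-ordering
   flip endo < epi) and then frozen. I_NaL enters the total ionic current
   (voltage equation) only; the Na⁺ mass balance keeps the original flux
   list. Adding it to dNa_i/dt loads the cell with sodium, suppresses
   forward Na⁺/Ca²⁺ exchange and inverts the HF calcium phenotype.

2. **Homogeneous scalings** (all cell types): g_K1 ×0.67, P_NaK ×0.90,
   g_bCa ×2.53, V_leak ×6.0, g_NaL ×3 (as above). "↓x %" means
   ×(1−x/100) and "↑x %" means ×(1+x/100).

3. **Heterogeneous scalings** (epi / M / endo): V_maxup ×0.70/0.60/0.55,
   K_NaCa ×3.00/2.65/2.65, g_CaL ×1.00/0.80/0.65, g_to ×0.30/0.30/1.00.

Cells are paced at 1 Hz (−52 pA/pF, 1 ms) until the beat-to-beat relative
change of APD₉₀ and of the Ca_i peak falls below 10⁻³ (at most 200 beats).
The model keeps drifting in Na⁺/K⁺ for several hundred beats; the 10⁻³
plateau is where the published single-cell values live, and it is
insensitive to whether HF pacing starts from rest or from the NF steady
state (<1 % difference). With these choices the HF cells show the expected
phenotype: Ca²⁺ peak reduced by ≈ 39 % on average (raised diastolic level,
slowed decay), active-force peak reduced by ≈ 67 % with longer twitches,
and APD₉₀ 268→356 (epi), 272→344 (endo), 318→421 ms (M). The calcium-peak
reduction saturates near 40 % rather than 50 % because the 2004 SR release
flux `a_rel C_SR²/(b_rel²+C_SR²)+c_rel` is nearly insensitive to SR load
above ≈ 0.6 mM, which caps how strongly SERCA-down/leak-up remodeling can
depress the transient.

## Tissue electrophysiology

The deformation-modified bidomain equations are discretized with trilinear
hexahedra (consistent mass) on the structured wedge mesh, Crank–Nicolson
in time with Godunov splitting: Rush–Larsen cell update (gates by the
exponential closed form, concentrations and crossbridge states by explicit
Euler), then the parabolic solve for v, then the elliptic solve for u_e.
Conductivity tensors are transversely isotropic about the fiber direction
(σ_i = 3.0/1.0, σ_e = 2.0/1.65 mS/cm along/across fibers; ×0.7 in HF),
χ = 2000 cm⁻¹, C_m = 1 µF/cm², Δt = 0.05 ms, Δx = 0.5 mm. Deformation
enters as the pull-back J F⁻¹ D F⁻ᵀ of both tensors and a J-weighted mass
matrix, with F held fixed between mechanics updates. u_e is gauge-fixed to
zero weighted mean through a Lagrange multiplier. Linear systems use
prefactorized sparse LU by default; an ILU-preconditioned CG/MINRES path
is available (`solver="pcg"`) and agrees with the direct path to <10⁻³ mV.
Lumped mass and a monodomain operator (harmonic-mean tensor) exist behind
flags; the monodomain path doubles as an equivalence oracle for
proportional conductivity tensors.

Because the wedge is stimulated on its whole endocardial face with no-flux
lateral boundaries, the solution is planar; a 1-D transmural cable using
the cross-fiber conductivities reproduces the 3-D ACT/REP/APD profiles to
<1 ms and serves as the desk-scale surrogate for the dispersion tables.
The stimulus is a transmembrane current injection of −80 pA/pF for 2 ms on
the endocardial face (cable: the x = 0 node).

In a planar bidomain with scalar transverse conductivities the identity
u_e = −σ_i/(σ_i+σ_e) v + c(t) holds, so the transmural electrogram
u_e(epi) − u_e(endo) is proportional to v(endo) − v(epi): its T-wave sign
equals the repolarization order of the two surfaces. Here (and in the
repolarization table this geometry implies) the endocardium repolarizes
first in both NF and HF, so both conditions produce the same
(negative) T-wave sign without deformation; deformation amplifies the
T-wave amplitude in all conditions. A NF/HF sign contrast would require
the surface repolarization order to flip between conditions.

## Mechanics

Passive myocardium is the reduced transversely isotropic Holzapfel–Ogden
law Ψ = a/(2b)[e^{b(I₁−3)}−1] + a_f/(2b_f)[e^{b_f(I₄f−1)²}−1]·[I₄f ≥ 1],
with the fiber term disabled under fiber compression. Defaults
a = 0.496 kPa, b = 7.209, a_f = 15.193 kPa, b_f = 20.417 (the classic
transversely isotropic parameter fit of the law); HF multiplies all four
constants by 5. The compression switch is regularized over a 10⁻⁴ band in
I₄f (softplus blend) because its tangent-stiffness jump (2a_f at I₄f = 1)
makes Newton chatter when quadrature points sit exactly at the reference
state; outside the band the law is numerically unchanged.

Contraction is active stress, S_a = T_a^max T_a (f₀⊗f₀)/‖F f₀‖², with
T_a^max = 50 kPa. This stress is conservative — it is the C-derivative of
(T_a^max T_a/2)·ln I₄f — which the solvers exploit.

Near-incompressibility uses a three-field Q1/P0/P0 mean-dilatation
formulation (element-constant pressure and dilatation, statically
condensed; θ_e = element-mean J, p_e = κ(θ_e−1), volumetric energy
κ/2 (θ−1)² with κ = 10⁴ kPa chosen so that |J−1| < 10⁻² at the study's
peak loads). Quadrature is 2×2×2 Gauss.

The quasistatic solve ramps the active load over N_inc = 10 increments
with Newton iterations converged in the energy norm
(ΔE_k ≤ 10⁻⁶ ΔE₁). The consistent tangent is obtained by central
finite differences of the analytic element residual, all 48 perturbations
evaluated in one vectorized pass. Robustness around the soft low-strain
regime of the exponential law (where the load-controlled active-stress
problem passes near limit points) comes from three ingredients: a
per-transmural-slab homogeneous predictor (each slab solves the
closed-form uniaxial balance a(λx²−λy²)e^{b(I₁−3)} = T), a backtracking
line search that rejects element-inverting or residual-growing steps, and
an L-BFGS descent on the total potential energy as a rescue when Newton
leaves its basin of attraction. In the coupled time loop, mechanics is
re-solved every Δt_mec = 1 ms warm-started from the previous displacement
with a frozen-tangent Newton (tangent refreshed on stall, energy
minimization as fallback); the wall-clock cost is dominated by these
tangent refreshes.

Boundary conditions: zero normal displacement on the x = 0, y = 0, z = 0
and z = z_max faces (fibers along y, transmural axis x), which admit the
wall-thickening mode λ_x ≈ 1/λ_y, λ_z ≈ 1 and suppress rigid-body motion.
Wall thickening is 100 × (deformed − reference transmural extent)/
reference extent.

## Coupling and measurements

Explicit staggering: electrophysiology advances at Δt = 0.05 ms; every
1 ms the nodal T_a is interpolated trilinearly to Gauss points, mechanics
is re-solved, and the EP operators are reassembled with the new F (held
constant until the next mechanics step). Probe electrodes are material
points at the endo-/epicardial face centers. ACT is the first upward
crossing of −20 mV (linearly interpolated; a max-dv/dt rule exists behind
a flag and agrees within 1 ms), REP the 90 % return from peak toward the
pre-stimulus baseline, APD = REP − ACT, and disp X = max X − min X over
activated nodes. The T-wave window runs from "all nodes activated + 50 ms"
to the end of the record; the T-wave peak is the signed extremum in that
window. Everything is deterministic — repeated runs are bit-identical.

## Problem sizes

The package's standard desk-scale experiments are: single cells at 1 Hz
(≤200 beats); 19/27-node transmural cables (9/13 mm at 0.5 mm) over
1000 ms; quasistatic thickening on 1 mm meshes (9×9×9, 13×9×9 mm); and
coupled electromechanics on thin-cross-section wedges
(9(13) × 1 × 1 mm at 0.5 mm, 500–650 ms). The thin cross-section is not an
approximation for the planar protocol: with full-face stimulus, no-flux
lateral boundaries and x-only mechanics modes, the solution is independent
of the lateral extent, while coarsening dx beyond ≈1 mm conduction-blocks.
Full-section 1000 ms runs at dx = 0.5 mm use the same code paths and are
overnight-scale.

## Known limitations

- Stretch-activated channels, deformation-dependent C_m and χ, apex–base
  heterogeneity, fiber rotation, endocardial pressure loading and
  orthotropic passive terms are out of scope.
- The HF calcium-peak reduction saturates near 40 % (SR-release load
  insensitivity of the 2004 calcium subsystem, see above).
- Single-cell APD₉₀ sits 3–5 % below the published values of the cell
  model; transmural REP dispersion without deformation is correspondingly
  larger than wedge-preparation-calibrated references.
- The no-deformation T-wave sign cannot differ between NF and HF in this
  planar geometry (1-D identity above); only its amplitude and its
  amplification by contraction are meaningful here.
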