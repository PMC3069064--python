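# Methods

`ciliasim` simulates the interaction between the inner-hair-cell (IHC)
stereocilia bundle and the endolymph of the subtectorial space in two
dimensions, using the immersed-boundary (IB) method. This note documents the
model, the numerical scheme, the parameter choices that matter, and the known
limitations — including two places where the printed parameter set is
internally inconsistent and what this package does about them.

## Physical model

**Domain and boundaries.** The subtectorial space is a rectangle, 20 µm long
and 5 µm high (the subtectorial gap at the guinea-pig cochlear apex), filled
with endolymph treated as an incompressible Newtonian fluid (ρ = 1000 kg/m³,
ν = 0.7×10⁻² cm²/s). The bottom boundary is the reticular lamina (RL), which
performs a small orbital oscillation at 200 Hz; the top boundary is the
tectorial membrane (TM), horizontally stationary but sharing the RL's
vertical motion, so the gap height never changes. The side boundaries carry
the analytic oscillatory-channel (Stokes layer) profile of a bottom wall
oscillating beneath a stationary wall,

    u(y,t) = Re[ Û e^{iωt} sinh(k(H−y)) / sinh(kH) ],   k = √(iω/ν),

with zero vertical velocity. Because the Stokes penetration depth at 200 Hz
(≈ 33 µm) far exceeds the 5 µm gap, the channel flow is quasi-steady Couette
to a good approximation. Wall motion amplitudes (tens of nm) are far below
the grid spacing, so boundary motion is imposed as velocity data on the fixed
rectangle (standard linearization).

**Bundle.** Three rows of stereocilia stand on the RL in the middle of the
domain, represented as chains of Lagrangian points spaced r₀ = 75 nm apart.
Row heights are 4.5, 2.925 and 1.575 µm (ratios 1 : 0.65 : 0.35 of the
tallest, which is sized to leave a 0.5 µm clearance under the TM). Diameters
taper linearly from 400 nm at the base to 200 nm over the lower third of each
row, then stay at 200 nm. The tallest row stands on the −x side: with the RL
dragging fluid rightward at drive phase 180°, the rows lag leftward relative
to their bases, and this orientation is the one in which that lag tensions
the tip links — matching the stated convention that peak stretch occurs at
phase 180°.

Rows are elastic fibers with stretching and bending energies, both derived
from the effective Young's modulus of F-actin, E = 2.3 GPa:

* stretching: ½·(EA/r₀)·(|ΔX|−r₀)² per segment, A = πd²/4 with the local
  (tapered) diameter;
* bending: ½·(EI/r₀)·(θ−θ₀)² per interior triad, I = πd⁴/64, θ the signed
  exterior angle (θ₀ = 0: straight rows at rest).

Forces are the exact negative gradients of these energies (verified against
central differences in the test suite), so internal forces conserve momentum
identically.

**Links.** Two gated tip links (tallest↔middle "upper", middle↔shortest
"lower") and six ungated horizontal top connectors join the rows, all
Hookean with stiffness 5×10⁻⁴ N/m. Tip links run from the shorter row's tip
obliquely up to the taller row's shaft two lattice points (150 nm) higher;
with the default inter-row spacing of 80 nm this realizes the 170 nm
tip-link rest length exactly at rest (√(80² + 150²) = 170), so all links are
built at zero extension. Links resist compression symmetrically; the gate
responds only to positive (tensile) signed tension, since compression must
never open it.

**Gating spring.** Each tip link carries a threshold state machine: when its
signed tension reaches the threshold, the gate opens and the link rest length
ramps up by A = 5 nm over the elongation time τ₀ (default 1 µs). The open
state latches for the rest of the run (an optional hysteresis reclosure rule
is available but off by default, since nothing constrains it). The elongation
itself is implemented as a kinematic event: the gating-spring end of the link
(the shorter row's tip, where gating springs sit) is driven 5 nm along the
link axis over τ₀ by a stiff target spring while the fluid step is subcycled
at τ₀/5. This is deliberate: the spring stiffness of 5×10⁻⁴ N/m means a pure
rest-length jump changes the force balance by only ~2.5 pN and moves nothing
measurably — there would be no "oar stroke" and no vorticity. The vortex
physics requires the boundary to actually sweep the 5 nm in τ₀, and the
kinematic ramp is the minimal way to express that.

**Anchoring.** The two basal points of each row (y = 0 and y = 75 nm) are
prescribed to follow the RL exactly (a clamped base standing in for the
rootlet). They do not exchange force with the fluid through the IB transfer:
the basal reaction is carried by the lamina, whose no-slip motion the wall
boundary condition already imposes on the fluid there. This replaces the
more common stiff-target-spring anchoring, which at these stiffnesses is
explicitly unstable at any affordable time step and adds nothing physical
for wall-attached points.

## Numerical scheme

**Fluid.** MAC staggered grid; the nominal 78 nm spacing is realized as
h = 78.125 nm so that 256×64 cells tile 20×5 µm exactly ("full"
resolution; "half" and "quarter" multiply h by 2 and 4). Time stepping is
Chorin projection: explicit centered advection (the Reynolds number is
~10⁻³; a Stokes-mode switch drops advection entirely for verification),
Crank–Nicolson diffusion (the diffusion number ν·dt/h² is 10²–10³ here, far
beyond any explicit limit), and a pressure projection solved by a DCT-based
fast Poisson solver with homogeneous Neumann conditions (direct solve;
post-projection divergence is at rounding level, ~10⁻¹⁵ relative). The
implicit Helmholtz operators are constant-coefficient and separable, so they
are solved directly by sine-transform diagonalization (DST-I along the
interior-Dirichlet direction, DST-II along the ghost-folded wall direction);
a sparse-LU backend is kept as a cross-check and agrees to rounding. Verification: the no-bundle oscillating-wall channel matches the
analytic Stokes-layer solution with second-order grid convergence
(relative error 3×10⁻³ at ny = 16, 7×10⁻⁴ at ny = 32).

**IB transfer.** The standard Peskin four-point kernel (piecewise-algebraic
form) spreads Lagrangian point forces to both MAC face families and
interpolates velocities back. The kernel satisfies the partition-of-unity
and first-moment identities, so constant and linear fields interpolate
exactly and spreading is the exact adjoint of interpolation (total force
conserved to rounding). Points within 2h of an edge have their stencils
clipped with a logged warning; in practice only the wall-adjacent basal
region is affected.

**Time step and subcycling.** The macro step is dt = T/1000 = 5 µs at
200 Hz; observables are recorded at every macro step. The explicit elastic
coupling of the IB method is stiffness-limited well below dt for F-actin
fibers, so each macro step subcycles the coupled fluid–structure update; the
default substep counts (10/24/64 for quarter/half/full resolution, scaled if
the macro step is changed) are the empirically determined stable values.
Halving the substep width changes the tip-link peak phases by under one
degree, so the subcycled solution is converged in the solver step.

**Units.** All state is kept in SI double precision. The magnitudes in play
(10⁻⁷ m grid, 10⁻⁶ s steps, 10⁻¹³–10⁻⁷ N forces) sit comfortably within
double range, and avoiding a nondimensionalization layer removes a class of
unit bugs; the verification suite (energy gradients, analytic channel flow,
adjointness) confirms that no precision problem arises.

## Scenarios and drive

The drive convention fixes signs: at phase θ = ωt = 180° the RL is displaced
maximally rightward and downward, i.e. dx = −A_h·cos θ, dy = +A_v·cos θ
(an optional vertical phase offset turns the trajectory into a genuine
ellipse; it defaults to zero because only the θ = 180° convention is
constrained). Default amplitudes are A_h = 25 nm and A_v = 5 nm for the
"98 dB" label — the measured orbit is not available, so these are calibration
placeholders, and the calibration procedure (match the tallest row's
horizontal amplitude and phase) is the user-facing way to set them. A
half-cycle raised-cosine ramp multiplies the displacement so the flow starts
from rest; velocities are exact derivatives of the ramped displacements, and
the side profiles are likewise differentiated exactly so the corner values
are consistent at every instant. The first two cycles are discarded as
transient.

Three scenarios: `normal` (5 µm gap), `widened_gap` (10 µm gap — the TM
moves away, rows unchanged, clearance 5.5 µm), and `horizontal_only`
(A_v = 0). Each differs from `normal` in exactly one way.

## Behavior of the model, and two parameter inconsistencies

**Tip-link phasing is resolution-sensitive.** The clearance between the
tallest row and the TM (0.5 µm) is the controlling geometric feature; at
quarter resolution it spans < 2 grid cells and the computed peak-stretch
phases sit near 210°–220°, while at half resolution (3.2 cells across the
clearance) they move to ≈ 160°–195°, bracketing the expected 180°, and a
full-resolution run (`ciliasim run --resolution full`, ~40 minutes) brings
both links to within ten degrees of 180°. Half resolution is the default
for phase-sensitive analyses and for the acceptance script as the best
accuracy/runtime point on one CPU.

**Row length change is orders of magnitude below 10 nm, necessarily.** The
model predicts cycle-peak arclength changes of ~0.3 nm, not ~10 nm, and this
is structural rather than numerical. Two independent arguments: (i) both
walls share the vertical motion, so a uniform vertical translation of fluid
plus bundle is an exact solution of the coupled problem up to side-boundary
corner mismatches that decay like exp(−πx/H) (≈ 2×10⁻³ at the bundle) —
vertical drive therefore cannot produce O(A_v) relative motion anywhere near
the bundle, and the `horizontal_only` scenario is nearly indistinguishable
from `normal` (lower-link peak tension ratio ≈ 1, not < 0.1); (ii) free-end
doubling of a longitudinal pulse requires the rod's wave travel time to be
comparable to the drive period, i.e. an effective axial wave speed ~10⁴
times lower than E = 2.3 GPa F-actin provides; at 200 Hz a 4.5 µm actin rod
is deep in the quasi-static regime and tracks its base. The doubling itself
is real physics and is verified by the package's 1D longitudinal-pulse
oracle (ratio exactly 2 at a stress-free end); it just cannot be excited in
this geometry at these parameters. The 10 nm figure would require a
substantially softer effective axial stiffness than the printed modulus
implies (the full calibrated parameter table is not available).

**Gate threshold vs link stiffness.** The printed gating threshold
(26.5 nN) together with the printed link stiffness (5×10⁻⁴ N/m) implies
~53 µm of tip-link stretch to trigger — six orders of magnitude above the
nm-scale stretches the model produces (tensions are pN-scale). Both numbers
are implemented exactly as given and are configurable; with the default
threshold the gates simply never open. Because the package still needs to
study gating-spring events (vortex formation), scenarios support
`gate_trigger="auto"`: the threshold is armed at a configurable fraction
(default 0.9) of the peak tension observed during the discarded transient
cycles, guaranteeing a physically timed opening event near the tension peak
of the first analyzed cycle. A plausible resolution of the inconsistency is
that the threshold was meant in pN, but the package does not silently assume
that.

**Nanovortex.** With an auto-triggered gate the 5 nm / 1 µs elongation
stroke injects vorticity of order (A/τ₀)/√(πντ₀) ≈ 3×10³ s⁻¹ — the
impulsively-started-plate (Rayleigh) scale — into a region of order the
viscous penetration depth √(ντ₀) ≈ 0.8 µm. The simulation shows a
counter-rotating pair with |ω| ≈ 5×10³ s⁻¹ within 1 µm of the gate at the
end of the ramp, decaying within a few macro steps, consistent with that
estimate. Vortices are detected as vorticity extrema enclosed by a
streamfunction level set that closes inside a 1 µm window after subtracting
the window-mean flow (Galilean invariant; pure shear yields no detections).

## Transport estimates

Closed forms, reported by `diagnostics.transport_estimates`:

* diffusive Ca²⁺ supply rate D/l² = 1.38×10⁴ s⁻¹ (D = 4×10⁻⁶ cm²/s,
  l = 170 nm), diffusion time l²/D = 72 µs;
* required influx from a 500 pA transduction current with a
  concentration-proportional carrier split (20 µM Ca²⁺ vs 160 mM K⁺) and
  divalent charge: ≈ 2×10⁵ ions/s. This is an order-of-magnitude bookkeeping
  number — the split rule is the simplest defensible assumption, and other
  published splits give up to ~10⁶/s;
* critical elongation time: solving 1/ω(τ) = l²/D with the Rayleigh
  vorticity gives τ_crit = (A·l²/(D√(πν)))^{2/3} ≈ 0.39 µs — the gating
  spring must elongate in well under a microsecond for vortical mixing to
  beat diffusion.

## What the scenario runs do and do not show

The runs demonstrate: stable nm-scale fluid–structure coupling at the
printed geometry and elasticity; tip-link stretch phasing that brackets the
180° convention once the clearance is resolved; gating-spring elongation
events generating sub-micron closed-streamline eddies at the predicted
vorticity scale; and deterministic, bit-reproducible trajectories. They do
not reproduce: the ~10 nm row length changes, the dependence of lower-link
tension on the vertical drive component, or the strict widened-gap
compression of the upper tip link — all of which trace to the effective
softness/inertia calibration that the printed parameter set does not pin
down (see the inconsistency notes above). The synthetic drive is a
parametric stand-in for a measured orbit; absolute amplitudes are
calibration knobs, so quantitative tension magnitudes should be read as
relative, not absolute.

## Numerical choices and degenerate inputs

* Poisson gauge: zero-mean pressure; incompatible (nonzero-mean) right-hand
  sides raise rather than being silently projected, except inside the
  projection step where the mean is removed by construction.
* Coincident consecutive Lagrangian points raise a degenerate-segment error.
* Peak phases are refined by quadratic interpolation through the three
  samples around the discrete maximum.
* Checkpoints are restricted to macro-step boundaries with no elongation
  ramp in flight; a resumed run reproduces the uninterrupted trajectory to
  rounding.
* The tip-link "stretch" observable is measured against the closed-gate
  rest length, so an open gate appears as a rest-length offset rather than
  as spurious negative stretch; compression is plotted as negative values.
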