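# ciliasim

Two-dimensional immersed-boundary simulation of the inner-hair-cell (IHC)
stereocilia bundle in the oscillatory flow of the subtectorial space.

Mammalian hearing begins when sound-driven motion of the reticular lamina
(RL) and tectorial membrane (TM) shears the endolymph around the IHC hair
bundle, tensioning the tip links that gate mechanotransduction channels.
`ciliasim` is a research code for people studying this coupling: it resolves
nanometer-scale motion of the three stereocilia rows, their tip links and
gating springs inside a micron-scale fluid domain, and extracts the
observables that matter for transduction — tip-link stretch as a function of
drive phase, per-row kinematics, nanovortex formation at gating-spring
elongation events, and order-of-magnitude Ca²⁺ transport estimates.

## Model

The endolymph obeys the incompressible Navier–Stokes equations on a
rectangular domain (20 µm × 5 µm, the subtectorial gap at the guinea-pig
apex),

    ρ (∂u/∂t + u·∇u) = −∇p + µ ∇²u + f,     ∇·u = 0,

where `f` is the force density the bundle exerts on the fluid. The bundle is
a set of Lagrangian elastic chains **X**(s,t) (three stereocilia rows, 75 nm
point spacing, linear diameter taper over the basal third) coupled to the
grid by the immersed-boundary method with the Peskin four-point kernel δ_h:

    f(x,t) = Σ F(s,t) δ_h(x − X(s,t)),      ∂X/∂t = Σ u δ_h(x − X) h²,

with **F** the negative gradient of discrete stretching and bending energies
(E = 2.3 GPa F-actin; stretching ½(EA/r₀)(|ΔX|−r₀)², bending
½(EI/r₀)(θ−θ₀)²). Two gated tip links (rest length 170 nm) and six
horizontal top connectors (stiffness 5×10⁻⁴ N/m) join the rows; a tip-link
gate opens at a tension threshold and elongates the link by 5 nm over ~1 µs
— the sudden stroke that sheds a sub-micron vortex with Rayleigh vorticity
scale (A/τ₀)/√(πντ₀).

The RL (bottom wall) performs an orbital 200 Hz oscillation (maximally
rightward and downward at drive phase 180°); the TM (top wall) is
horizontally fixed and vertically co-moving; the sides carry the analytic
oscillatory Stokes-layer channel profile. Time stepping is Chorin projection
with Crank–Nicolson diffusion and a DCT fast Poisson solver on a MAC grid
(nominal spacing 78 nm). See `docs/methods.md` for the full model
description, parameter table provenance, and known limitations.

## Worked example

Run the normal-gap scenario at quarter resolution (about two minutes) and
analyze it:

```
$ ciliasim -v run --scenario normal --gate-trigger auto --out runs/normal
INFO ciliasim.simulation: cycle 1 done: |u|max=1.793e-05 m/s, CFL=2.87e-04, wall=32.2s, |T|max=4.580e-13 N
INFO ciliasim.simulation: cycle 2 done: |u|max=1.765e-05 m/s, CFL=2.82e-04, wall=63.2s, |T|max=4.646e-13 N
INFO ciliasim.simulation: auto gate thresholds armed: ['1.507e-13', '4.371e-13']
INFO ciliasim.simulation: gate opened: lower_tip_link at t=1.275500e-02 s (phase 198.4 deg)
...
$ ciliasim analyze runs/normal
upper_tip_link: peak stretch 0.252 nm at phase 198.2 deg
lower_tip_link: peak stretch 1.116 nm at phase 199.6 deg
row tallest: peak rotation 5.366e-03 rad, peak length change 0.287 nm
row middle: peak rotation 6.171e-03 rad, peak length change 1.556 nm
row shortest: peak rotation 4.086e-03 rad, peak length change 1.768 nm
```

Both tip links develop sub-nanometer periodic stretch (tension ~0.1–0.5 pN
at the 5×10⁻⁴ N/m link stiffness), peaking once per cycle in the half-cycle
where the lamina is displaced rightward; rows rotate by ~5 mrad about their
insertions, and the gating-spring elongation event visibly stretches the
rows it pulls on (the nm-scale length changes of the middle and shortest
rows above). At half resolution (`--resolution half`), which resolves the
0.5 µm clearance between the tallest row and the TM, the peak phases move to
≈160°–194°, bracketing the nominal 180° synchronization phase. With
`--gate-trigger auto` the tip-link gate opens near the tension peak and the
elongation stroke sheds a counter-rotating vortex pair (|ω| ≈ 5×10³ s⁻¹
within 1 µm of the gate), the "nanovortex" that can stir Ca²⁺ past the
diffusion limit:

```
>>> from ciliasim import transport_estimates
>>> est = transport_estimates()
>>> est.diffusion_rate      # Ca2+ diffusive supply rate D/l^2, 1/s
13840.8...
>>> est.tau_crit            # gating-spring elongation time to beat diffusion, s
3.9e-07
```

The library surface mirrors the pipeline: `geometry` (bundle construction),
`elastic` (forces/gates), `ib` (spreading/interpolation), `fluid`
(projection solver), `scenario` (drives and boundary conditions),
`simulation` (the coupled engine), `diagnostics` (traces, kinematics, vortex
detection, transport estimates), `io`/`cli` (persistence and the `ciliasim`
command).

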