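# Methods

## Model

`locsim` integrates the underdamped Langevin equation for N spherical
colloidal particles in a low-Reynolds-number fluid,

    m dv/dt = (k_B T / D(r)) [v_f(r,t) − v] + √2 D^{1/2}(r) W(t) + F_ext(r,t),

with per-particle mass m, radius r_o, a position-dependent *diagonal*
diffusion tensor D(r), fluid velocity v_f, white noise W, and the vector
sum of configured external force fields F_ext.  Assumptions baked into
the model:

* Particles are rigid spheres; no rotation or orientation state.
* Drag is Stokesian and per-particle; hydrodynamic coupling *between*
  particles is neglected (dilute suspensions).
* The suspension is isothermal; the only wall that hinders diffusion is
  the bottom substrate at z = 0 (side walls act through collisions only).
* Collisions are perfectly elastic and instantaneous; walls are
  infinitely massive.

### Discretization

The equation is discretized by Euler–Maruyama with the drag evaluated at
the *new* velocity (implicit drag).  Solving for v_{i+1} gives, per
component, with Λ = mD/(k_B T Δt):

    v_{i+1} = Λ/(1+Λ) v_i + 1/(1+Λ) [ v_f + √(2/Δt) √D w_i + D F/(k_B T) ],

followed by the Euler–Cromer position step r_{i+1} = r_i + v_{i+1}Δt.
Because Λ/(1+Λ) < 1, the homogeneous map is a contraction and the scheme
is unconditionally stable in Δt (verified in the tests at 10× the usual
step).  The noise prefactor √(2/Δt)·√D is fixed by requiring that the
overdamped limit Λ → 0 reproduce the Brownian-dynamics displacement
statistics: mean v_f Δt + D F Δt/(k_B T), per-axis variance 2DΔt
(fluctuation–dissipation against the drag k_B T/D).  This is checked by
Monte-Carlo in the test suite.  D^{1/2} is the element-wise square root
of the diagonal tensor.

For micron-scale beads at Δt ≈ 10 ms, Λ ≈ 6·10⁻⁵: the dynamics are
effectively overdamped and the initial velocity is forgotten within one
step.  Initial velocities therefore default to zero; Maxwell–Boltzmann
initialization is available behind a flag (`thermal_velocities`) but only
adds a meaningless one-step transient.

### Hindered diffusion

D(r) = D₀·diag(H∥, H∥, H⊥) with D₀ = k_B T/(6πηr_o) and, in u = r_o/z,

    H∥ = 1 − (9/16)u + (1/8)u³ − (45/256)u⁴ − (1/16)u⁵,
    H⊥ = (6 + 2u) / (6 + 9u + 2u²).

Both factors are evaluated at the clamped height max(z, r_o): during a
prediction step a particle may transiently dip below contact before the
collision pass corrects it, and the clamp keeps the factors meaningful
there (the formulas are never evaluated below contact otherwise).  The
tensor is evaluated at the *pre-step* position, before the velocity
update.

### Collisions

Detection is purely geometric on the predicted positions: pair (p,q)
collides iff |r_p − r_q| < r_{o,p} + r_{o,q}; particle–wall iff the
signed wall distance is below r_o.  Resolution is a single pass per time
step, events in ascending index order, particle–particle before wall
(a particle in both gets the pair resolution first, then the
reflection).  The resolved velocity replaces the predicted one and the
position is re-advanced from the pre-step position, r_adj = r_i +
v_adj Δt.  Residual overlap after the single pass is tolerated — there is
no iterative relaxation and no re-detection within a step.  Coincident
centres (probability zero under continuous dynamics) fall back to a +z
normal with a logged warning.

The particle–particle normal-component update is
v_p' = v_p − [2m_q/(m_p+m_q)] ((v_p−v_q)·n̂)n̂ (and symmetrically for q),
the unique form that conserves both momentum and kinetic energy for
unequal masses; the m_q → ∞ limit recovers the wall reflection
v − 2(v·n̂)n̂.

### Force fields

* **Gaussian trap**: u(r) = −(4/3)πr_o³·A_d·exp(−|r−c|²/w²).  The well is
  attractive (A_d is a depth); force = −∇u analytically.  A_d is
  configured in k_B T·μm⁻³ and converted with the medium temperature.
  Defaults follow the bundled fixture: A_d = 120 k_B T μm⁻³, w = 10 μm,
  gate 1 s < t < 8 s.  Peak restoring force on a 2 μm bead: 1.43 pN at
  radius w/√2.
* **DEP**: F = 2πε₀ε_m r_o³ Re(C̃M) ∇|E|².  ∇|E|² comes either from a
  regular-grid import (second-order central differences + multilinear
  interpolation, clamp-to-edge outside the domain with a warning) or an
  analytic field with a closed-form gradient.  Re(C̃M) per particle is
  either a fixed scalar or resolved once at the drive frequency from a
  multi-shell model — C̃M is constant during a fixed-frequency run, so it
  is cached at startup.
* **Gravity/buoyancy**: (4/3)πr_o³(ρ_p − ρ_f)g along −z, optional.

### Multi-shell dielectric model

Layers are homogenized from the core outward: with γ = R_outer/R_inner
and K = (ε̃_in − ε̃_sh)/(ε̃_in + 2ε̃_sh),

    ε̃_eq = ε̃_sh (γ³ + 2K)/(γ³ − K),

until one sphere remains; ε̃ = ε_r − jσ/(2πfε₀) throughout.  The bundled
yeast data (`src/locsim/data/yeast_cells.yaml`) is a two-shell cell
(cytoplasm + 8 nm membrane + 0.22/0.25 μm wall, 3 μm total radius).
Layer values start from the standard yeast multi-shell literature set;
because published layer values vary and the effective sphere is the
physically observable quantity, the cytoplasm/wall parameters are
calibrated (once, at build time of the data file) so the homogenized
sphere reproduces the reference effective properties at 5 MHz —
ε_eff = 199.94 / 18.82 and σ_eff = 0.36 / 0.013 S/m for viable /
non-viable cells.  The medium conductivity (7.86·10⁻⁴ S/m, a
low-conductivity sorting buffer) is the joint best fit to the reference
CM pair; the model then gives Re(C̃M) = +0.9465 / −0.2488 (reference:
+0.945 / −0.25), magnitude ratio 0.263.  No single medium conductivity
reproduces both reference CM values exactly given the effective
properties above; the residual (≤ 0.002) is inherent to that
over-determination.

## Devices and fixtures

**Optical trap** — 4 polystyrene beads (ρ = 1055 kg/m³; radii 1.5, 2.5,
2, 2 μm) in water (η = 8.9·10⁻⁴ Pa·s, T = 300 K) above a floor at z = 0;
trap gated ON for 1 s < t < 8 s; Δt = 10 ms, 12 s.  Initial positions
are sampled in a ±10 μm × ±10 μm × [3, 20] μm box: the trap has a finite
capture range (beads much farther than the well width never fall in), so
the fixture injects within it; the capture-fraction statistic reported by
the acceptance script refers to these conditions.

**DEP sorter** — floor, 50 μm-high channel walls: a wide inlet chamber
funnels into a straight channel over a tapered electrode array
(length 350 μm, gaps 16 μm, outer widths 20 μm, middle taper 46→70 μm,
recorded as polygon metadata), splitting past x = 170 μm into a centre
channel (|y| < 30 μm) and two slanted channels with slope 30/150.  Flow
is the piecewise model: (150, ±30, 0) μm/s in the slanted outlet
channels (x > 170 μm, ±y > 30 μm), (150, 0, 0) μm/s otherwise, with
strict inequalities (boundary points take the default branch).  An
optional box moving-average smoothing (default kernel 20 μm when enabled;
0 = raw piecewise field, used everywhere in the tests) regularizes the
region boundaries.  17 + 17 cells of 3 μm radius are injected in
x ∈ [−480, −200] μm, y ∈ [−280, 280] μm, z ∈ [6, 80] μm; Δt = 5 ms, 6 s.
Walls block at all heights by default (particles can be injected above
the 50 μm wall top; a `full_height_walls=False` switch caps blocking at
the physical height).

### The |E|² surrogate

The real device field requires an electrostatics solver (out of scope;
the grid import exists for exactly that hand-off).  The bundled analytic
surrogate places two Gaussian ridges (σ_y = 12 μm) along the electrode
gap centrelines y = ±y_c(x), y_c tapering 31→43 μm over the electrode
span, windowed in x by logistic edges (10 μm) and decaying as
exp(−z/25 μm) above the planar electrodes.  It reproduces the *structure*
of the real field — maxima in the gaps, decay with height and distance —
not its magnitudes, and is labelled qualitative throughout.  The ridge-top
intensity default (3·10⁹ V²/m², of order (volts/gap)² for the 4 V drive
after z-averaging) is chosen so the peak DEP drift of a viable cell is a
few hundred μm/s: strong enough to deflect cells within the electrode
transit time, slow enough that one Δt = 5 ms step stays well below the
ridge width (no overshoot oscillation).

## What the synthetic conditions do and do not show

The paper-scale sorter injection spans the whole inlet chamber; cells
entering far from the centreline (|y| ≳ 50 μm) or high above the
electrodes (z ≫ 25 μm) pass outside the surrogate field's influence and
are routed by geometry alone — with the surrogate those runs demonstrate
transport, collisions, and channel routing, not dielectric selectivity.
The quantitative separation statistics are therefore computed under
scaled conditions: 5 + 5 cells injected inside the electrodes' region of
influence (y ∈ [−30, 30] μm, z ∈ [6, 20] μm), 10 seeds.  There the two
cell types separate cleanly (viable → side channels, non-viable → centre,
each ≥ 80% by test contract and 100% in practice).  Passing these tests
shows the coupled physics (CM sign selectivity + flow + geometry)
produces the sorting behaviour; it does not validate absolute force
magnitudes for the real electrode field — those enter only through the
imported |E|² grid.

The trap and diffusion tests likewise validate statistics (MSD slopes,
variance ratios H⊥/H∥, capture/release behaviour), not individual
stochastic trajectories, which are seed- and field-dependent by nature.

## Numerical choices

* All internal computation in SI; configuration files use μm / s / V
  with conversion at the boundary.
* One master seed spawns independent per-particle noise substreams
  (`numpy` SeedSequence), plus one stream for initialization — adding
  particles or diagnostics never shifts another particle's noise.
  Runs are bit-reproducible for a fixed seed.
* Problem sizes: the fluctuation–dissipation check uses one bead for
  10⁵ steps; collision conservation uses 10⁴ random impacts; behavioural
  checks average 3 trap seeds and 10 sorter seeds.  These sizes put the
  3σ statistical bands well inside the asserted tolerances.
* Degenerate inputs: coincident centres → +z fallback normal; vanishing
  shell-homogenization denominator (γ³ = K) and zero CM denominator →
  explicit degenerate-parameter errors; non-finite integration state →
  a numerical-failure error carrying the step index.
* Log cadence: every step up to 2·10⁵ particle-steps, then decimated
  (full resolution behind `log_every=1`).

## Known limitations

* No inter-particle hydrodynamic coupling; no lubrication forces; no
  two-wall (slit) hindrance corrections; no rotational diffusion.
* Single-pass collision resolution tolerates small residual overlaps in
  dense packings (visible as bead clusters slightly inside contact).
* The conservative-gradient optical force model omits scattering and
  other non-conservative components (relevant mainly to near-field
  traps).
* No fluid flow induced by the non-uniform electric field
  (electrothermal / AC-electroosmotic effects) and no Navier–Stokes
  solving; flow models are prescribed.
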