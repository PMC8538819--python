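# Methods

This note documents the models, numerical choices and limitations of
`mnpsteer`: what is simulated, which parameters matter, what the scaled-down
study conditions are, and what passing tests do and do not establish about
the laboratory system.

## Mesoscale particle model

Each bead is a uniform magnetizable sphere in a quiescent viscous fluid.
The force balance sums five terms: the electromagnetic actuation force, the
inter-particle point-dipole force, Stokes drag, Hertzian normal contact and
gravity/buoyancy.  Brownian forces are excluded by construction; the model
is valid only for beads above 0.5 µm diameter and the `Particle` type
enforces that bound (an explicit override exists for exploratory use).

**Actuation force.** `F_MF = (4/3)π μ1 R³ Msat (ĥ·∇)H` with `μ1` the fluid
permeability.  Water is effectively non-magnetic, so `μ1` defaults to the
vacuum value `μ0`; with `Msat` and `H` in A/m this yields newtons.  The
contraction `(ĥ·∇)H` acts along the unit field direction; for the
physically realisable (curl-free) fields used here it equals `∇|H|` scaled
by the moment, which is what the oracle tests check against.

**Dipole force.**  The standard point-dipole interaction,

```
F_i = (3 μ1 |m_i||m_j| / 4π r⁴) [ (m̂_i·m̂_j) r̂ + (r̂·m̂_j) m̂_i
      + (r̂·m̂_i) m̂_j − 5 r̂ (r̂·m̂_i)(r̂·m̂_j) ]
```

with moment magnitudes in the prefactor and unit vectors in the bracket,
and the sign fixed so that head-to-tail co-aligned moments attract — the
prerequisite of chain formation.  The implementation is verified as the
exact negative gradient of the dipole interaction energy.

**Moment model.**  The bead moment is induced by the local field:
`|m| = V · min(χ|H|, Msat)` aligned with `H`, with `χ = 3` — the
demagnetization-limited effective susceptibility of a high-permeability
sphere.  At the coil fields relevant here (1.75–13 mT, i.e. 1.4×10³–10⁴
A/m) the beads sit on the linear branch, which makes the dipole force —
and hence aggregation speed — grow with coil current, the central
experimental observable.  The fully saturated model is available as the
`χ → ∞` limit.  During field-off intervals the moment drops to a
configurable remanence fraction (default 0): this is the premise by which
discontinuous actuation promotes disaggregation.

**Material constants.**  The silica-coated magnetite beads' saturation
magnetization, density and contact stiffness are not published; the
defaults are chosen once as realistic composite-bead values:
`Msat = 5×10⁴ A/m`, `ρ_p = 2500 kg/m³`, and a Hertz stiffness derived from
an effective modulus of 10 MPa at the default radius.  All are plain
configuration entries.

## Two-coil field model

The field is calibrated to a measured table of axial field magnitude (mT)
versus coil current (1–5 A) and distance from the coil face (1–10 mm), for
two coils facing each other across a 10 mm region of interest.  The
interpolant is monotone piecewise-cubic (PCHIP) in distance — preserving
the printed ordering without overshoot — and linear in current; every
printed node is reproduced bit-exactly.  The printed 4 A / 2.5 mm entry
(25 mT, below the 3 A value of 25.5 mT) violates current-monotonicity; the
fixture keeps the printed value and the validator emits a warning rather
than silently editing measured data.  Queries outside the table range
raise unless explicitly flagged, in which case the current axis is
extended linearly (needed for the 0.5 A sweep point) and the distance axis
is clamped at the table edge.

The spatial model is quasi-1D: the field points along the coil axis toward
the active coil with the calibrated magnitude at the axial distance to
that coil, and the gradient tensor is the analytic derivative of the
interpolant (cross-checked against central differences away from the
interpolant knots, where a finite difference is itself meaningful).

Waveforms: `static` holds one coil on (the baseline of the aggregation
experiments and the comparator for the disaggregation claim); `dma`
alternates equal magnitudes at frequency Fr.; `a-dma` drives the strong
coil at H for 2/3 of each period and the weak coil at h for 1/3 (2:1
activation-time ratio); `da-dma` appends an all-off interval Tdis to each
a-dma cycle.  Tdis has no published value and is a free parameter.

## Integrator

The default mode is overdamped: for micron beads in water the velocity
relaxation time `m/(6πηR)` is ~10⁻⁷ s, far below any affordable time step,
so velocity is the mobility times the non-drag force sum.  The inertial
mode uses semi-implicit Euler with the drag term implicit in the velocity
update — explicit drag would be unconditionally unstable at mesoscale
steps — and converges to the overdamped trajectory from below (verified to
<1% on a two-body fixture at dt = 1 µs).

Two numerical guards make mesoscale steps of 2×10⁻⁴ s possible:

* a per-step displacement cap (default 0.25 of each bead's own radius) —
  the dipole force diverges as r⁻⁴ at approach, and the cap turns the
  final capture into a bounded-speed approach without affecting far-field
  drift;
* a pairwise overlap projection after each move (damped Jacobi sweeps)
  that returns contacting pairs to touching distance.  The Hertzian
  contact equilibrium relaxes on ~ns scales that no mesoscale dt can
  resolve; integrating it with forces alone either penetrates or
  oscillates.  The Hertz law is retained exactly at the force level (and
  within each step); the projection is a geometric stabilisation and can
  be disabled.

Box walls act as rigid Hertzian planes (the same contact law against a
plane); there are no periodic boundaries.  A blow-up guard raises a
`StabilityError` naming the offending pair whenever any overlap exceeds
half the smaller radius.  Forces are accumulated in ascending particle-id
order and every update is a pure float64 array operation, so trajectories
are bit-reproducible for a given configuration.

Neighbor search uses a uniform cell grid with cell edge equal to the
cutoff; for moderate particle counts (≤ 512) an equivalent vectorized
all-pairs scan is used instead, purely for speed — both paths are tested
against a brute-force oracle and return identical pair sets.

## Aggregate analysis

An aggregate is a connected component of the contact graph whose edges
join pairs with center distance ≤ `tolerance·(R_i+R_j)` (default 1.05).
Chain length is the maximal end-to-end extent — max over member pairs of
center distance plus both radii; a singleton reports its own diameter.
The laboratory measurement was a 2D microscope projection, so an optional
projection mode drops one axis before measuring.  Sweep rates are
normalized by a nominal aggregate length of 6.2 µm (the measured
nominal-condition value).

The suspension volume (µL) → particle count mapping is not physically
determined at desk scale; the package documents a linear convention of
4 particles/µL (30 µL ↦ 120 beads) used only to label density sweeps.

## Scaled-down study conditions

The trend protocols in `mnpsteer.experiments` run 100 beads in a 28.5 µm
box (mean spacing ≈ 6 µm, chosen so that chains form within the first
second of static actuation, as observed in vitro) at dt = 2×10⁻⁴ s, three
seeds per condition.  Chain lengths are time-averaged over short windows
(rather than read from one frame) because the mean jumps when marginal
contacts cross the tolerance threshold.  Exposure-time checkpoints are
placed at 0.1, 0.37 and ~1.1 s: without Brownian motion the scaled-down
system freezes into a repulsive chain pattern and stops coarsening after
~1 s, so the growth phase is where the time ordering is meaningful.
Current and diameter sweeps are evaluated at 0.6 s for the same reason.

What these sweeps show: the *orderings* — chain length grows with exposure
time, coil current and bead diameter, and discontinuous actuation yields
shorter chains than static actuation at equal total time.  What they do
not show: the absolute micrometre values measured in the laboratory (the
bead material constants are unpublished), any effect mediated by Brownian
motion, flow, or polydispersity, and long-time coarsening beyond the
frozen state.

## Coarse-grained membrane crossing

The bilayer is a bead-spring surrogate: each lipid is a 4-bead planar
zigzag (head, mid, two tail beads) at its bonded equilibrium geometry;
two mirrored leaflets with heads outward, tail tips separated by the tail
LJ contact distance; lateral spacing 7.8 Å with a small seeded per-lipid
jitter.  The equilibrium angle is 165° rather than 180° because a
perfectly straight chain makes the torsion angle undefined; the dihedral
and improper minima are placed at the planar-trans geometry.  Edge-column
lipids are tethered harmonically to their build positions — the atomistic
reference uses periodic boundaries, the coarse engine uses an anchored
patch instead.

All six potential forms (bond, angle, dihedral, improper, LJ with CHARMM
switching between 10 and 12 Å, cutoff Coulomb) have analytic forces that
are verified as exact negative gradients by finite differences.  Mixing
uses Lorentz–Berthelot rules.  Particle–membrane interactions use LJ plus
Coulomb truncated at 16.7 Å (plain truncation; the discontinuity at the
cutoff is negligible at these charge separations).

The particle is rigid (its internal forces are never evaluated): surface
sites on a Fibonacci sphere carry the Fe3O4 partial charges in a 1:2:4
tetrahedral-Fe : octahedral-Fe : O cycle, making every 7-site block — and
hence the particle — exactly neutral.  Aggregates are two tangent spheres
with the center line along the membrane normal (orthogonal) or in the
membrane plane (parallel).  Rigid-body rotation under the membrane torque
is integrated explicitly and can be frozen for controlled comparisons.

Pulling follows the constant-velocity protocol: a 1-D harmonic guide of
stiffness 15 kcal/mol/Å² moves along the membrane normal at 0.03–0.05
Å/fs; those values are treated as guide velocities.  Membrane beads evolve
under BAOAB Langevin dynamics at 310 K (friction 0.05 fs⁻¹, dt = 2 fs in
the study protocol); a Langevin thermostat replaces the
isothermal–isobaric ensemble of the atomistic reference because the
anchored coarse patch has no meaningful barostat target, and it is stable
at coarse resolution.  The membrane-on-particle axial force is averaged
over short strides and recorded against guide displacement until the
particle clears the far leaflet; the AUFDC is its trapezoidal integral.
The lost-bead fraction counts beads displaced beyond a detachment radius
(default 15 Å) outside the original bilayer slab.

What the coarse model reproduces: the orderings of crossing work —
aggregate > single particle at equal velocity, faster pulling > slower,
radius-doubled (8× volume) > single — and membrane integrity (< 1% lost
beads).  What it does not: absolute atomistic force magnitudes or the
atomistic percentage increase in work between carrier sizes; receptor
(protein) mediation; solvent.

## Determinism and reproducibility

Every stochastic element (initial placement, membrane jitter, Langevin
noise) flows from an explicit integer seed through `numpy` Generators;
identical seeds give bit-identical trajectories and curves.  CLI runs
write a manifest with a SHA-256 hash of the canonical configuration, the
seed and library versions.

## Known limitations

* No Brownian motion, hydrodynamic coupling, or flow: the mesoscale
  droplet is static and aggregation freezes once dipole barriers dominate.
* The quasi-1D field model has no off-axis components; an ideal-dipole 3D
  coil model is out of scope for the calibrated table.
* Contact is normal-only Hertz (no tangential friction, no adhesion).
* The coarse membrane has no solvent, no receptors and no barostat; its
  force scale is set by generic coarse-grain constants, not by fits to
  the atomistic system.
* The 0.5 A sweep point relies on linear extension of the calibration
  below its smallest measured current.
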