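# Methods

This note records the model assumptions, parameter choices, numerical
decisions and known limitations of `weedspray`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Scope and idealizations

The package models one rosette weed under one hollow-cone nozzle at desk
scale. Leaves are uniform rectangular-section cantilevers clamped at the
stem; taper, torsion, turgor effects and large-deflection beam theory are
out of scope. Droplet flight before leaf contact is drag-free projectile
motion (the 0.3 m flight is far shorter than the ~12 s Stokes relaxation
time of a 2 mm droplet, so drag is negligible there); drag enters only the
dynamic simulation. The full CFD external flow field (k–ε turbulence,
velocity maps, turbulence intensity) is deliberately not reimplemented: the
continuous phase is a constant downward jet inside the spray cone and still
air outside. Values that only a full finite-element fluid–structure run can
produce (peak fluid velocities, turbulence intensities) are therefore not
claimed by this package.

## Static deflection: two readings of the closed form

The closed-form leaf deflection is stated in the literature as a double
integral over the leaf's width and length whose integrand itself contains
the full width and length — divergent if integrated as written. Two modes
are exposed:

* `literal` (default): the integrand is evaluated at the full leaf
  dimensions and multiplied by the leaf area A = b l — the engineering
  shorthand consistent with how the total leaf area is used elsewhere in
  that derivation. The elastic part is then
  y(x) = (2 F₀ sin θ cos θ_t x⁴ + G cos β x²) / (4 E b h_l³ cos² θ).
* `beam`: the textbook Euler–Bernoulli cantilever under the uniform
  transverse surface load q = (F₀ sin θ cos θ_t + G cos β)/(2 A cos² θ),
  line load w = q b, tip deflection w l⁴ / 8EI.

On the template leaf the two tips differ by a fixed factor ≈ 9.42
(literal/beam), pinned by a regression test; they are alternative readings,
not competing fits. The reported `tip_drop` is the transverse tip
deflection projected onto the vertical (× cos β), compared against the
parallel-to-ground threshold l sin β.

Two elastic moduli circulate for this weed (272.5 MPa in-text, 222.85 MPa
tabulated) without reconciliation; the deflection model defaults to the
former and the plant template to the latter, both switchable. θ is always
computed as 90° − β, never hard-coded.

## Parcel volume and the operating-pressure window

The impact force F₀ = π ρ R v₁² V / 2 leaves the parcel volume V
ambiguous. Two conventions are provided:

* `single_droplet` — V = (4/3)πR³ of one droplet (default at the
  ballistics level, since the force law is framed per particle);
* `aggregate` — V = Q Δt / ρ, the liquid discharged over an aggregation
  window Δt (default 1 s, the duration of a single field spray pass).

With per-droplet volume, one R = 1 mm droplet at 0.4 MPa yields
F₀ ≈ 5.3 µN and an elastic tip descent of ~35 nm — eight orders below the
19.2 mm parallel-ground threshold; the solver would need ~10⁸ kPa-scale
pressures and correctly raises its no-solution error. The solve pipeline
therefore defaults to `aggregate`, under which the window is finite:
≈ 13.5–23.2 MPa across the two reach endpoints. This is still ~35–60×
above the reference 0.383–0.389 MPa window; the solver reports the
deviation factor rather than adjusting constants, because no unit- or
volume-convention we could justify closes that gap. Similarly, the orifice
law with C_d = 0.6 and R₁ = 0.5 mm gives 0.01304–0.01314 kg/s over the
reference pressure window, not the reference 0.011–0.0113 kg/s; both flow
windows appear side by side in the solve report. The orifice Q is treated
as volumetric and multiplied by ρ to express kg/s, and ΔP = P (gauge).

Solver numerics: matched endpoints (reach directly beneath the nozzle with
incidence β; slant reach at the cone edge with incidence β + γ), bisection
on log P over (10², 10⁹) Pa to a 1 Pa interval, root residual checked below
1 µm of tip drop. The bracket top sits at 10⁹ Pa so that the aggregate-mode
roots (≈ 1.3–2.4 × 10⁷ Pa) are inside it. The cone angle is rounded *up* to
the next 5° (33.69° → 35°), matching nozzle catalogue granularity.

## Reduced-order dynamic simulation

Each leaf carries one modal coordinate: the first cantilever bending mode,
with ω₁ = (1.8751)² √(EI/μl⁴), effective modal mass 0.25 m_leaf
(tip-normalized), K = ω₁²M, and modal damping ratio ζ = 0.05 by default
(the damping matrix is not specified anywhere; 5 % is a typical vegetation
value and drives the observed decaying swing after peak deformation).
Point impacts are projected onto the mode by the static tip-unit shape
φ(x̂) = x̂²(3 − x̂)/2. Integration is Newmark average-acceleration
(unconditionally stable); free vibration matches the analytic damped
oscillator's amplitude envelope within 0.5 % over 0.5 s at the 1 ms step
(phase accumulates the usual O((ωΔt)²) Newmark period error, ~0.3 % here,
which the envelope comparison is insensitive to).

Particles follow the drag/gravity force balance with the exact
exponential-relaxation velocity update and semi-implicit position update;
t_r defaults to the Stokes value ρ_p d²/(18 μ). Impact outcomes: normal
approach speed above 15 m/s → splash; rebound speed (restitution e = 0.3
times approach speed) at or below the 2 m/s adhesion capture speed →
deposit; otherwise rebound. All three constants are configurable because
no measured values exist for this system; with e = 0 every sub-splash
impact deposits, which the unit tests exploit. Momentum transfer to the
leaf is m v_n per deposit and (1 + e) m v_n per rebound/splash. The mass
ledger (airborne / deposited / rebounded / splashed / ground, with
out-of-domain arrivals folded into ground) balances the emitted mass to
1e-9 relative at every step.

Wall films grow by parabolic-cap deposits (central thickness from the
volume balance h₀ = r*²/2R with R = πr*⁴/4V; footprint r* = 2× droplet
radius by default), renormalized on the grid so deposited volume is
conserved exactly; the film loads its leaf with its own weight, projected
on the mode — the "pressure proportional to film thickness" coupling in
its simplest static form. The optional velocity term sometimes appended to
the film equation is dimensionally inconsistent (a speed added to a
thickness) and is omitted.

### Deformation index and stage classification

The deformation index ξ = (x_d − x_i)/x_i needs a mapping from the modal
tip displacement s to the horizontal leaf extent x_d. The default
(`rotation`) treats the leaf as inextensible and rigidly pivoted by s/l:
x_d = l cos(β − s/l), which is bounded by the geometric ceiling
1/cos β − 1 ≈ 0.195 at β = 33.22° and shrinks again past horizontal. The
alternative `small_angle` mapping, x_d = l cos β + s sin β, grows without
bound and reaches tan² β ≈ 0.429 at the parallel condition — the frame in
which reported indices up to ~0.43 at quasi-parallel deformation are
recovered. Reported field/simulation indices exceeding the inextensible
ceiling indicate an extent measurement in that transverse frame; we keep
the bounded mapping as the default because it cannot diverge for violent
impacts, and expose the other.

The four interaction stages ratchet monotonically: targeted movement until
the first impact; contact and diffusion until the sustained ξ reaches half
its parallel-condition ceiling; continuous coverage until the sustained tip
descent exceeds l sin β; strong impact and drainage beyond. "Sustained"
means a trailing mean of the modal displacement over a 50 ms window
(configurable; window → one step recovers the instantaneous rule). The
windowing matters: a single 4 mg droplet at ~24 m/s transiently swings a
45 mg top leaf past horizontal for a few milliseconds, but drainage is a
sustained-posture phenomenon, not a millisecond excursion.

### Problem sizes

Default runs use the printed coupling settings (T = 0.5 s, Δt = 1 ms) and
the droplet count implied by the operating point — ≈ 1 600 droplets of
R = 1 mm at 0.013 kg/s over 0.5 s, well under the 5 000-particle budget the
mass-ledger properties are audited at; a default run takes ~1.5 s on one
CPU. The R = 1 mm droplet radius is the printed value; real hollow-cone
nozzles at 0.4 MPa atomize far finer, which would multiply particle counts
by ~10³ — one reason the discrete model is run at desk scale only.

## Synthetic data

The plant builder reproduces the measured template exactly at zero jitter:
12 leaves in two layers (8 bottom at 35 × 15 mm, 4 top at 20 × 8 mm,
growth directions offset 45°), thickness 0.4 mm, β = 33.222°, stem
Ø 3 mm, density 700 kg/m³. Optional uniform multiplicative jitter (our
distributional choice; only means of five sampled plants are reported in
the source material) perturbs lengths and widths leaf-by-leaf. Modal
parameters derive from each leaf's geometry/material by the first-mode
construction above; leaf mass assumes uniform density over the rectangular
slab, since the blade's true mass distribution is unmeasured.

Droplet streams realize the target mass flow within 2 % as equal spheres
(count = round(Q·T/m_droplet)), uniform emission times, directions uniform
in solid angle inside the cone, exit speed from Bernoulli. Stain images
emulate water-sensitive paper as binary grids: deposit-driven stamping
(stain radius = 2× droplet radius — the dot-spread mapping is our choice,
configurable), or coverage-driven stamping that shrinks stains as the
remaining deficit shrinks and stops within 0.01 of each target, with the
measured ground truth stored in a sidecar. Images are plain-text PGM so
every artifact remains inspectable text.

What passing tests on these synthetics do *not* show: real leaves taper,
twist and shelter each other aerodynamically; real sprays are polydisperse
and drift; water-sensitive paper saturates and bleeds. The synthetic
round-trips validate the *statistics and bookkeeping*, not field realism.

## Degenerate inputs and tie-breaks

Zero flight time, zero pressure, zero-duration streams and empty images
all return exact zeros or empty series rather than erroring; β → 0 makes
the leaf perpendicular to the stem frame (cos θ = 0) and raises a
singular-configuration error; per-droplet solve mode raises a no-solution
error naming the unreachable endpoint. Coverage variance short-circuits
exact equality to return exactly zero (the σ = 0 ⇔ equality contract would
otherwise be broken by floating-point mean rounding). All randomness flows
through explicit integer seeds; identical seeds give bit-identical
simulation ledgers and images.
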