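# Methods

## Scope and model

`acoustopattern` simulates, in two dimensions, the patterning of small
(radius ≪ λ) spherical particles on the floor of a water-filled chamber
surrounded by a circular ring of phased ultrasound elements.  Three
layers make up the model:

1. **Linear acoustics.**  Each element is a baffled piston radiating a
   cylindrically spreading wave; the complex pressure at a grid node is
   the sum over elements of
   `S_w · exp(i k r) / (2π √r) · sinc(a π² sin θ / λ)` times the complex
   element drive.  `S_w` is a free calibration constant (default 1): all
   simulations normalize forces instead of pressures, so the absolute
   pressure scale never enters.  Reflections, reverberation and
   transducer electromechanics are not modelled (the physical device has
   matched, absorbing-backed elements).
2. **Gor'kov radiation force.**  `F_ac = −∇U` with
   `U = (4 r_p³/3)[f₁·½κ₀⟨p²⟩ − f₂·¾ρ₀⟨v²⟩]`, `⟨p²⟩ = |p̂|²/2`,
   `⟨v²⟩ = |v̂|²/2`, `v̂ = ∇p̂/(−iωρ₀)` by central differences.  The
   leading factor is implemented in the `4r³/3` form used by the device
   literature this package follows; the conventional `4πr³/3` is
   available (`prefactor="volume"`).  The two differ by a constant that
   force normalization removes, so every reported result is identical
   under either choice.
3. **Particle dynamics.**  The explicit update
   `x ← x + ẋΔt + F_eΔt²/m_v`, `ẋ ← ẋ + F_eΔt/m_v`, with
   `F_e = F_ac(x) − F_d(ẋ)`, virtual mass
   `m_v = (4/3)πr_p³(ρ_p+ρ₀/2)` and drag
   `F_d = 6πμ₀r_p√(1+3Re/16)·ẋ` (`Re = 2r_pρ₀|ẋ|/μ₀`), which is the
   quadratic-form drag `½ρ₀πr_p²C_d|ẋ|²` with
   `C_d = (24/Re)(1+3Re/16)^0.5` and reduces exactly to Stokes drag as
   `Re → 0`.  Forces between grid nodes are bilinear; positions are
   clamped to the chamber radius (minus one particle radius) with the
   velocity zeroed at contact.

### Sign conventions

The time-harmonic convention is `exp(−iωt)`, so an outgoing wave carries
the spatial factor `exp(+ikr)`.  This is the unique choice under which
the focusing phase law `φₙ = 2mπ(n−1)/N − k rₙ` (as used by the device)
aligns all element contributions at the focus; the conjugate convention
would require `+k rₙ`.  All time-averaged observables (|p|, ⟨p²⟩, ⟨v²⟩,
U, F) are invariant under global conjugation, so nothing downstream
depends on the choice.

### Neglected physics

Acoustic streaming, substrate friction, wall lubrication and
inter-particle (surface-tension) forces are omitted, matching the model
scope of the device experiments this simulator mirrors.  The absence of
static friction matters qualitatively in one place: arbitrarily small
forces move particles here, whereas a real slide pins particles below a
force threshold.  Consequences are noted under "Recipes" below.

## Parameters

| quantity | symbol | default | note |
| --- | --- | --- | --- |
| sound speed (water) | c₀ | 1500 m/s | 25 °C |
| density (water) | ρ₀ | 997 kg/m³ | |
| viscosity (water) | μ₀ | 0.89 mPa·s | |
| particle radius | r_p | 45 µm | polystyrene sphere, 90 µm diameter |
| particle density | ρ_p | 1050 kg/m³ | f₂ = 0.0342 |
| particle sound speed | c_p | 2047 m/s | f₁ = 0.4901 |
| elements | N | 64 | equally spaced, inward normals |
| chamber diameter | D | 10.98 mm | |
| frequency | f | 2.35 MHz | |
| operating wavelength | λ | 0.644 mm | device value; see below |
| element width | a | chord pitch 2R·sin(π/N) ≈ 0.54 mm | not separately specified by the device; contiguous-ring assumption |
| force ceiling | F_max | 10 nN | all reference runs |
| low-impulse dwell | Δt_q | 1 ms | applied impulse 10 pN·s |
| grid spacing | | λ/20 | ≤ λ/10 enforced (force finite differences) |
| integration step | Δt | min(Δt_q/20, τ_visc/50) ≈ 15.7 µs | τ_visc = m_v/(6πμ₀r_p) = 0.78 ms; steps above τ_visc/10 are rejected |

**Wavelength discrepancy.**  c₀/f = 0.638 mm, while the device operates
at a printed λ = 0.644 mm (implying c ≈ 1513 m/s).  `build_circular_array`
derives λ = c₀/f by default; `device_array()` pins the printed 0.644 mm
for device-matching runs, and a JSON config may override either.  Which
value the original device software used internally cannot be determined;
both are exposed and none of the qualitative results depend on the 1 %
difference.

**Force normalization.**  `normalize_force` rescales a field so its
maximum magnitude equals F_max.  The workspace takes that maximum inside
0.8× the chamber radius: pressure (hence force) diverges like 1/√r near
the elements, and anchoring the scale to that boundary layer would leave
the working region essentially force-free.

## The switching regimes and the 1D bench

The two-state bench applies `F_q(x) = −F_max sin(2k(x − x_q))` with
equilibria at x₁ = 0 and x₂ = λ/8.  The λ/8 pattern shift is the ideal
two-counter-propagating-source result for a π/2 source phase offset; the
original 1D source geometry is under-specified (a λ/4 pattern shift
would cancel the two force fields exactly), so the shift is a bench
parameter and every regime measure is expressed relative to the actual
equilibria separation, making conclusions shift-independent.

Motion per cycle is the mean per-cycle position range over a 100-cycle
window with the first 20 % discarded.  Classification uses 5 % / 95 % of
the separation (config-overridable; the underlying boundaries are only
ever defined graphically).  The measured curve collapse — motion depends
on (F_max, Δt_s) only through their product — holds to 4.5 % of the
separation across the sweep (three force ceilings 2.5/5/10 nN, dwells
0.1–100 ms, 3.6 decades of applied impulse).  Strict *pointwise relative*
collapse fails below Δt_s ≈ τ_visc, where the particle velocity never
reaches terminal and per-cycle motion scales as F·Δt²/τ rather than
F·Δt; this inertial regime contributes sub-micron absolute deviations.

## Clearing tools

* **Conveyor.**  Two opposing 11-element sub-apertures with `k·r_sw`
  curvature correction synthesize a plane standing wave; stepping the
  phase offset ±2π/3 (added on one side, subtracted on the other) moves
  the node lines by an effective λ/6 per state change, λ/2 per 3-state
  loop.  A trapped particle follows the nearest node, so its λ/2 loop
  displacement completes when the loop re-enters its first state.
* **Focus sweep.**  A unidirectional raster of focal points (0.1 mm
  spacing) in the intermediate regime pushes particles out of a
  rectangle; two passes empty it in simulation.
* **Bessel-order cycling.**  The first high-pressure ring of an order-m
  vortex sits at the first maximum of J_m(kr).  Under the Gor'kov model
  everything inside that ring is pulled toward the dark core, so
  *decreasing* orders ratchet particles inward (agglomeration) and
  *increasing* orders plough the annulus between the initial and final
  ring radii outward while the core — and any pattern inside it — is
  protected.  Clearing an entire region therefore starts at a low order
  (small core); the 9→20 cycle is the pattern-preserving variant.
  Chirality alternates between repetitions; off-centre origins double
  the repetition count.

## Recipes

Letter recipes stage the tools as: Bessel-down 20→7 agglomeration (high
impulse, 2 repetitions, alternating chirality) → low-impulse skeleton
twin traps (12 cycles) → adaptive per-particle clearing → final trap
reinforcement.  Per-particle clearing distinguishes stragglers inside
the pattern radius — nudged onto the nearest skeleton line by brief
(12 ms) focused-point pushes placed 0.1 mm behind the particle — from
stragglers outside it, which an order-1 vortex trap drags radially to
the chamber edge in 0.1 mm steps; skeleton reinforcement is interleaved
every 8 removals.  The 12 ms × 10 nN setting measures 0.91 of the bench
separation: the top of the intermediate regime, fast enough to move one
particle, brief enough not to unsettle the pattern.

This staging is this package's own sequencing of the published toolset
(the original full field sequences exist only as deposited data).  Two
variants that fail in a friction-free model are worth recording: bulk
Bessel up-cycles or long vortex drags across a formed pattern destroy it,
because a chamber-spanning vortex's outer rings exert forces comparable
to the (Q-fold diluted) trap forces and, without static friction, any
sustained force displaces particles.  The real device is more forgiving
precisely because friction pins sub-threshold particles.

Line recipes follow the published stage order (sweep below, sweep above
twice, counter-swept traps, 9→20 Bessel-up with reinforcement, traps,
static standing wave), with experimental drive voltages mapped to force
ceilings by F = 10 nN·(V/20 V)² (pressure ∝ voltage, force ∝ pressure²).
Reshaping moves trap targets by the published increments (0.1 mm
translation, 5° rotation, radius steps 0.5/0.25/0.12 mm by range) with
the trap sweep direction alternating each step.

## Metrics and the synthetic benches

Ensembles are uniform over the central 4 mm patterning region (the
field-of-view of the device figures), zero initial velocity,
reproducible bit-for-bit from the seed.  `fraction_outside` reports the
percentage of particles farther than an inclusion tolerance (default
λ/4) from the target skeleton *and* farther than an edge margin (default
2λ) from the chamber wall; both defaults are free metric parameters
written into every report header.

What the benches do and do not show: they exercise the same idealized
physics as the published simulations (instantaneous switching, perfect
phase/amplitude control, no friction or streaming), so agreement
demonstrates internal consistency of the impulse-control mechanism, not
hardware fidelity.  Letter skeletons are documented single-stroke
approximations sized to the published figures (the A is 2.6 mm tall);
with them, low-impulse patterning alone leaves ~78 % of 500 particles
off-pattern (the published figure for the authors' own skeleton is
60.1 %), and the full clearing recipe reaches 0.0 % off-pattern with all
500 particles on the skeleton.  The off-pattern gap for patterning alone
is insensitive to the inclusion tolerance and to doubling the patterning
duration; it reflects skeleton capture length, which cannot be matched
without the deposited field sequences.

### Problem sizes

Reference runs use 500 particles for letters (the published ensemble
size), 50 for the switched-vs-summed comparison, ≈15.7 µs integration
steps, a 125×125 grid for the central region and 323×323 for the full
chamber.  The acceptance script averages the patterning-alone metric
over 3 seeds and the full-recipe metric over 2.

## Numerical choices and degenerate inputs

* Grid spacing coarser than λ/10 is rejected at grid construction
  (force finite differences need ≥10 nodes per wavelength).
* The integrator refuses steps above τ_visc/10; the default is
  τ_visc/50, and state boundaries are landed exactly for uniform dwells
  by snapping Δt to divide the dwell.
* `sinc` is the unnormalized sin(x)/x with sinc(0) = 1.
* Zero-length lines get a single trap; zero-area sweep regions, empty
  schedules and empty recipes are legal and empty; empty ensembles make
  `fraction_outside` raise (the metric is undefined).
* An element lying within half an angular pitch of a twin trap's
  cancellation axis is switched off.
* Trap counts use nearest-integer rounding of 3L/λ (+1), the variant
  consistent with the published example counts; consequently the
  realized spacing can exceed λ/3 by at most a factor (1 + 1/(2·gaps)).
* The numba-accelerated integrator has a pure-numpy twin; the two are
  unit-tested to agree to 1e-12 relative.

## Known limitations

* 2D fields only; no out-of-plane motion, no reflections.
* No friction/streaming/inter-particle forces (see above for where this
  bites).
* Letter skeletons, hence absolute contrast numbers for
  patterning-alone runs, are approximations; contrast metrics are
  always reported against the package's own skeletons.
* The hardware driver's 0.074 s update latency is not emulated;
  schedules switch instantaneously.
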