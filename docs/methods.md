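# Model and methods

## The model

Each of N cells is a rigid ellipse (2D) or prolate ellipsoid (3D) with
semi-major axis `a` along its heading `ω_i ∈ S^{d−1}` and semi-minor
axis `b`, moving in a periodic box `[0, L)^d`. The only interaction is
an anisotropic excluded-volume repulsion. Crowding on cell i is
measured by the *tension*

    V_i = Σ_{j≠i} Φ(r_ij²),
    r_ij² = (‖x_j − x_i‖² − e² [(x_j − x_i)·ω_i]²) / b²,
    e² = 1 − b²/a²,

with the smooth compact-support kernel

    Φ(s) = (1/s) exp(−1/(1−s))  for 0 < s < 1,   Φ(s) = 0 for s ≥ 1.

`r_ij` is the centre distance normalised by cell i's elliptical extent
toward j: it equals 1 when j sits on i's ellipse boundary, and is
**asymmetric** (`r_ij ≠ r_ji`) because each cell measures in its own
body frame. The overdamped dynamics are

    dx_i/dt = c ω_i − α ∇_{x_i} V_i
    dω_i/dt = −β P_{ω_i^⊥} ∇_{ω_i} V_i ,      P_{ω^⊥} = Id − ω⊗ω,

self-propulsion at constant speed plus descent of each cell's own
tension; the projector keeps headings on the unit sphere. Closed-form
gradients (derived from the r² expression above and validated against
central finite differences to 1e−5 relative):

    ∇_{x_i} r_ij² = (2/b²) (e² (d·ω_i) ω_i − d),   d = x_j − x_i
    ∇_{ω_i} r_ij² = −(2e²/b²) (d·ω_i) d .

For round cells (e = 0) the orientational gradient vanishes
identically: circular cells never steer, which is the model's central
negative control.

### Indirect alignment

For two interacting cells at frozen geometry the heading-to-separation
angle θ_h obeys dθ_h/dt = −C sin 2θ_h with
C = (β e²/b²) Φ′(r_ij²) ‖d‖² ≤ 0, so θ_h = ±π/2 is stable: each cell
turns its heading orthogonal to the separation vector, without ever
reading the neighbour's velocity. In 2D this forces nearby headings to
become parallel or antiparallel — the seed of flocks (one sign) and
bidirectional streams (both signs). The library exposes the printed
convention (`steering_coefficient` ≤ 0 and the `C sin 2θ` law for the
complement/transverse angle) plus `heading_angle_rate` for the heading
angle; the simulator is held to this law within 2% in the tests.

## Order parameters

* polarization ψ = |⟨ω_i⟩|: 1 for a flock, ≈0 for balanced streams or
  disorder.
* nematic polarization γ = |⟨e^{2iθ_i}⟩| (2D): sign-blind axis order;
  ≈1 for flocks *and* streams.
* nematic order J (any d): from the second-moment matrix
  M = ⟨ω⊗ω⟩, J = (d λ_max − 1)/(d − 1); coincides with γ in 2D. The
  dominant eigenvector is the nematic mean direction (defined up to
  sign; cells are coloured by the sign of ⟨ω_i, Ω_nem⟩, ties broken
  positive). The printed γ formula lacks an explicit radical; the root
  is taken so that perfect alignment gives γ = 1, the convention every
  qualitative use (γ ≈ .9, threshold γ > .7) requires.
* size-weighted mean cluster size Σ_k |C_k|²/N over the connected
  components of the "minimum-image distance ≤ R" graph, R = 10 μm by
  default — the expected size of the cluster containing a random cell.

## Numerics

* **Integrator.** Explicit Euler with projection-by-normalisation of
  the headings; positions wrapped each step. First order (verified by
  Richardson extrapolation on a seeded two-cell collision).
* **Step size.** Default dt = 0.01 h. The choice was set by a
  convergence study at the stiffest published regime (α = 100 μm²/h,
  β = 0.1 1/h, N up to 2000 in L = 300 μm): final-state order
  parameters are unchanged between dt = 0.01 and dt = 0.005, while
  dt = 0.05 visibly corrupts the dynamics — a colliding pair overshoots
  by several μm per step, which acts as strong angular noise and
  suppresses the slow (β = 0.1) alignment entirely. 3D runs use
  dt = 0.02 (checked against dt = 0.01 at N = 1000–2000, L = 70 μm).
* **Singularity guard.** Φ diverges like 1/s as two centres coincide;
  the normalised squared distance is floored at ε = 1e−6 before
  evaluating Φ, Φ′, capping forces when random initial conditions place
  centres arbitrarily close. Final states are insensitive to ε
  (ε = 1e−12 reproduces the same order parameters).
* **Neighbour search.** Since r_ij² ≥ ‖d‖²/a², pairs farther than `a`
  cannot interact; forces use a periodic cell list (uniform bins of
  size ≥ a, counting-sorted, each unordered pair visited once and
  accumulated in both body frames), falling back to all-pairs for small
  or tight boxes. Cell-list and all-pairs evaluations agree to 1e−12
  and the all-pairs kernel doubles as the brute-force oracle in tests.
* **Determinism.** A single seeded `numpy` Generator per run; sweep
  replicates derive per-run seeds from `SeedSequence([base, iα, iβ,
  rep])`. Identical (seed, config) ⇒ bit-identical trajectories on one
  platform.
* **Degenerate inputs.** Coincident centres are handled by the ε floor;
  non-finite states abort with the offending cell index; empty
  orientation sets are rejected by the statistics.

## Initial conditions and fixtures

`init_random` draws positions uniformly and headings isotropically
(2D: uniform angle; 3D: normalised Gaussians). `init_flock` /
`init_stream` build non-overlapping states (rejection sampling with a
capacity bound; pairwise centre distance > a guarantees r_ij > 1 for
every heading) with a common heading, or two counter-moving lanes.
These are the fixture generators: a perfect flock must be transported
rigidly (tested), a prepared stream probes metastability of the
bidirectional state.

The eccentricity sweep varies shape at constant area product
a·b = 16 μm², matching the reference pair (a = b = 4 μm) vs
(a = 5.5, b = 3 μm ⇒ e = 0.84), so shape is not confounded with
packing fraction.

## Phase diagrams

`run_sweep` runs seeded replicates per (α, β) grid point (defaults:
8×8 near-geometric grid over α ∈ [10, 200] μm²/h, β ∈ [0.1, 10] 1/h,
5 replicates), records final-time statistics, smooths each statistic
with a hand-written 2-D loess (local quadratic regression, tricube
weights over the `span` = 0.75 nearest fraction of points,
range-normalised coordinates, fitted values clipped to the statistic's
range), and labels regions: flock ψ > 0.8; stream γ > 0.7 and ψ ≤ 0.8;
a scattering overlay where the mean cluster size < 600. The three
published criteria are not mutually exclusive, so scattering is
reported as an overlay and flock takes precedence over stream for the
exclusive label.

## What the simulations do and do not reproduce

The synthetic experiments are the model's own study conditions — there
is no external data. At the reference scales the package reproduces:

* the circle-vs-ellipse contrast (Table-1 parameters, N = 1000,
  t = 1000 h: round cells stay disordered, ψ < 0.1; elongated cells
  flock, ψ > 0.95);
* rigid transport of perfect flocks, exact heading conservation for
  round cells and for β = 0;
* the two-cell indirect-alignment law quantitatively.

Two genuine discrepancies remain, both documented rather than tuned
away (the published integration scheme and step size are unreported):

1. **2D basin selection at high density.** With a convergence-validated
   integrator the 2D dynamics at α = 100, β = 0.1 either polarise into
   flocks or freeze in disorder at N ∈ {1500, 2000}, whereas the
   published account reports bidirectional streams (ψ ≈ 0.2 at
   N = 1500; ψ ≈ 0, γ ≈ 0.9 at N = 2000). Prepared streams *are*
   perfectly metastable here (γ = 1.0, ψ = 0.0 held through t = 1000 h
   at N = 2000 — the energy-landscape picture of stream locking holds),
   so the difference is purely which basin random initial conditions
   select. No examined variant reaches spontaneous streams: symmetrised
   total-V forces (destroys even the low-density flock), ε floors down
   to 1e−12, dt from 0.05 down to 0.005, β from 0.1 to 10, α from 10
   to 200.
2. **Ordering timescale, especially 3D.** At β = 0.1 in the 70 μm 3D
   box the nematic order J is still ≈ 0 at t = 1000 h but reaches 0.97
   by t ≈ 5000 h (N = 1000); at β = 1 the same system orders by
   t ≈ 600 h. The published curves reach J ≈ 1 by t = 1000 at β = 0.1,
   i.e. the implementation's alignment is a factor ≈ 4–5 slower than
   reported. The two-cell steering law here is verified against the
   analytic rate to 2%, and the published derivation of that law
   itself carries a factor-2 ambiguity between its displayed lines, so
   the end states agree while the clock does not.

Acceptance checks tied to the stream statistics and to the 3D values at
t = 1000 therefore miss the published numbers, and the test suite
records this openly. Conclusions resting on axis alignment as an end
state (γ, J → 1; flock-region shrinkage with density; metastability of
streams) reproduce; the polarization level at N ≥ 1500 and the 3D
order parameters *at t = 1000 specifically* do not.

## Limitations

Rigid shapes (no deformation, division or death), no adhesion, no
contact inhibition; a single homogeneous population; first-order
integration (no event detection at contact); phase-diagram smoothing
span and grid resolution are package defaults, not published values.
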