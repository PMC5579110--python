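# Methods

## Model

The package simulates conserved two-phase dynamics of a concentration
field f on a static curved surface Γ. The dimensionless evolution is the
Cahn–Hilliard (CH) equation, or the Cahn–Hilliard–Cook (CHC) equation
when thermal fluctuations are included:

    ∂f/∂t = (1/Pe) ∇ₛ·(ν(f) ∇ₛμ) + ξ,    μ = g′(f) − Cn² Δₛf,

with mixing energy g(f) = f²(1−f)², so the pure phases sit at f = 0 and
f = 1 and the spinodal region (g″ < 0) is 0.5 ± 1/√12. Two mobilities
are supported: constant, ν = 1 (transport through both bulk phases), and
degenerate, ν = 4f(1−f) (transport confined to interfacial regions; the
implementation clamps ν at zero from below because a semi-implicit scheme
lets f overshoot [0, 1] by O(Cn) near interfaces, and a negative mobility
would make the transport operator ill-posed). The free energy is
E[f] = ∫ (g(f) + (Cn²/2)‖∇ₛf‖²) dA; the dimensionless gradient-energy
coefficient is Cn², consistent with μ containing −Cn²Δₛf. The conserved
noise ξ is Gaussian, white in time, with spatial covariance shaped like
−Δₛ of a delta (one surface Laplacian: the divergence-form construction
below realizes exactly that), and intensity σ.

Assumptions: the surface is static (phase dynamics do not feed back on
the shape), f has no hydrodynamic coupling, and the noise respects the
fluctuation–dissipation form only to discretization accuracy — the tests
therefore check conservation, mean, and σ-scaling rather than exact
spectral balance.

## Discretization

Geometry is implicit. The two shipped shapes are analytic signed
distance functions: the unit sphere, and a dumbbell (spheres of radius
0.75 at x = ±1.125 joined by a cylinder of radius 0.375; its min-union
SDF is not a true distance near the interior skeleton, so closest points
near the sphere–cylinder crease are handled with explicit junction-circle
candidates and validated against a brute-force surface sampling in the
tests). Fields live on the narrow band of grid nodes with |φ| ≤ w.

Surface operators use the closest point method:

    M  = E₁ L  + α (E₃ − I),    α = 6/h²,

where E₁/E₃ interpolate band fields to closest points with tensor-product
linear/cubic polynomials, L is the 7-point Cartesian Laplacian, and the α
side condition pins solutions to be constant along normals. The
variable-coefficient version replaces L with a conservative face-flux
discretization of ∇·(ν∇·) with arithmetic-mean face mobilities (this
choice reduces exactly to L at ν ≡ 1 and keeps the stencil compact;
harmonic averaging was the alternative and is not implemented). ν on the
band is obtained by evaluating the mobility at the extended concentration
(mobility-of-extension); for ν = 4f(1−f) and an exactly extended f the
two orderings coincide.

Band width: `build_band` defaults to the conservative 6√3·h, but all run
configurations use w = 4h, the tight bound for the composite operators —
an E₃ stencil around a closest point reaches at most 2√3·h ≈ 3.46h, and
the Laplacian rows consumed through E₁ reach (√3+1)h ≈ 2.73h. Stencil
completeness is enforced with a hard error at assembly, so an
insufficient band cannot fail silently.

Time stepping is semi-implicit BDF2 on the split (μ, f) system: the
linear operators are implicit, g′ is evaluated at the extrapolated
predictor f̂ = 2fⁿ − fⁿ⁻¹, and ν inside the variable-coefficient block
also uses f̂ (the time level feeding ν is not dictated by the block
structure; the predictor is the consistent second-order choice). The
first step is backward Euler with f̂ = f⁰ (no second history level
exists yet); second-order behaviour starts at step 2. Each step solves
the 2×2 block system with GMRES (relative tolerance 1e−8 by default,
restart 30) using the approximate block-LDU inverse as preconditioner;
the Schur complement S = I + (2Cn²Δt/3Pe)·M·Mᵛ is approximated either by
the identity (adequate when Cn²Δt/h⁴ is small, as with the reference step
Δt = 5.12e−3·h) or by a frozen incomplete LU of the constant-mobility
S = I + κM², computed once per run. The preconditioner only affects
iteration counts, never the solution; a test verifies preconditioned and
unpreconditioned solves agree.

After each linear solve the fields are re-extended (one application of
E₃, keeping them constant along normals), and the concentration is
rescaled by β = M₀/∫f dA so the surface-integrated amount equals its
initial value exactly; β-correction after re-extension is equivalent to
the reverse order because E₃ is linear, and guarantees the post-step
mass. Surface integrals use a smoothed one-dimensional delta of the
signed distance (cosine kernel, half-width 1.5h, with the |∇φ| factor for
the non-exact dumbbell SDF); the kernel width is a choice validated by
the sphere-area oracle (second-order convergence to 4π).

Noise realization: at each band node's closest point two standard
normals build a tangential vector ρ = ρ₁t + ρ₂b in the node's
deterministic tangent frame (t = normalize(n × e_k) with e_k the axis
least aligned with n, b = n × t); each Cartesian component is extended
with E₃, a centred divergence is taken, re-extended, and scaled by
√(σ ν(f)/(h²Δt)) with ν evaluated at the current field (explicit,
Itô-style placement). Draws are Philox counter-based in (seed, step):
independent across steps, bitwise reproducible, order-independent across
ensemble members. Drawing per band node (rather than per unique surface
point) induces correlation along each normal fibre, which is harmless
because only closest-point values enter the surface dynamics.

Initial condition: mean concentration 0.3 with an i.i.d. uniform
perturbation of amplitude 0.01 attached to grid nodes; each band node
takes the draw of the node nearest its closest point, making the field a
function of the closest point alone — exactly constant along normals and
exactly within the stated amplitude (a polynomial extension of i.i.d.
draws would overshoot it). A Gaussian perturbation is available behind a
switch.

## Observables and statistics

R̄ = A/L with A = ∫f dA and L = ∫‖∇ₛf‖ dA, using projected centred
Cartesian gradients (P = I − n⊗n) of the extended field. For an
equilibrium tanh interface the cross-profile integral of ‖∇ₛf‖ is 1, so L
is the total interface length and R̄ ≈ (domain radius)/2 for circular
domains. The growth exponent is the OLS slope of ln R̄ vs ln t over a fit
window; windows are configuration keys with defaults matching the regime
boundaries of each study (sphere general [0.1, 10]; degenerate-mobility
CHC [0.1, 0.8]; dumbbell early [0.02, 0.2] and late [1, 10]). Domain
counting thresholds f at 0.5 (the double-well maximum) and counts
6-connected components of the thresholded band, which maps one-to-one to
surface domains because extended fields are constant along normals.
Ensembles report mean, sample sd (n−1) and CV; the lognormal fit is MLE
on logs (n denominator) with a parametric KS test at 5%, with a stricter
Lilliefors variant available.

## Flat-space reference

A pseudo-spectral CH/CHC solver on the periodic square serves as the
oracle for the coarsening law without curvature: first-order semi-implicit
stepping with the biharmonic term and a convex splitting (stabilization
constant s = 2 ≥ max g″) implicit in Fourier space, the nonlinearity and
the variable-mobility flux explicit. Its role is asymptotic (exponents),
not trajectory accuracy, so first order in time suffices. The
one-dimensional closed form f_eq(x) = ½[tanh(x/(Cn√2)) + 1] is used for
stationarity and interface-energy checks (energy per unit interface
length Cn√2/6).

## Reduced-scale study design

The reference configuration (N = 129, Δt = 5.12e−3·h, t_end = 10, 64
realizations per case) is multi-day on one CPU; it ships as runnable
configs in `examples/configs/`. The test suite and the acceptance script
use reduced problem sizes chosen once, from resolution arguments, as the
package's desk-scale study:

- Operator convergence: N ∈ {33, 65} spheres (exact spherical-harmonic
  eigenvalues −2 and −6).
- Conservation/dissipation: N = 49, 500 steps, Cn = 0.04 — this keeps
  the full-scale ratio of interface width to grid spacing (≈2.4 cells);
  at a coarser-than-full-scale grid the full-scale Cn would put less than
  one cell across an interface and produce resolution artifacts.
- Sphere coarsening ensembles: N = 33, Cn = 0.05 (again ≈2.5 cells per
  interface), Δt = 2e−3, t_end = 2, growth fit over [0.3, 2], three
  realizations per case. The spinodal growth rate scales as 1/Cn², so
  segregation completes near t ≈ 0.3 and a genuine coarsening window
  remains. For the CHC case the noise intensity is rescaled as
  σ = 1e−5·(h/h₁₂₉)²: the competition between noise and degenerate
  mobility is governed by the ratio √(σν)/h ÷ ν, and this scaling keeps
  that ratio equal to the full-scale configuration's on the coarser grid
  (σ itself enters the discrete forcing only through √σ/h). At this
  scale the absolute exponents sit below the full-scale values (shorter
  window, stronger curvature relative to domain size); the qualitative
  orderings — constant mobility coarsens faster than degenerate, and
  noise accelerates degenerate-mobility coarsening — are the reduced
  study's claims.
- Flat coarsening law: 256² torus, Cn = 8e−3 (≈5 cells per interface),
  Δt = 2e−3, 8 seeds, fitted over t ∈ [0.2, 2]: earlier times are still
  segregating, later times leave too few droplets for a clean power law.

What the reduced studies do and do not show: they exercise every code
path of the full-scale configuration (same operators, scheme, noise
construction, analytics) and reproduce the signs and orderings of the
physical effects; they do not reproduce the full-scale exponent values,
which need the N = 129 ensembles shipped as Tier-2 configs.

## Numerical choices and degenerate inputs

- GMRES: rtol 1e−8 (1e−6 for ensemble runs), restart 30, max 200
  restarts; non-convergence is a hard error with the residual reported.
- A uniform field has no interface: R̄ raises, and run recording stores
  NaN for such samples (the initial homogeneous state).
- β-correction requires positive current mass; zero/negative mass is a
  hard error rather than a silent sign flip.
- The sphere centre has no unique closest point; it is mapped to an
  arbitrary surface point and can never lie inside a valid band.
- Incomplete interpolation stencils and missing Laplacian neighbours are
  hard errors naming the offending node.
- Determinism: band ordering is lexicographic; all randomness flows
  through explicit seeds (Philox counters for per-step noise,
  SeedSequence spawning for ensemble members); σ = 0 runs are bitwise
  reproducible, and the CHC path with σ = 0 is bitwise the CH path.

## Known limitations

- The surface is static: no coupling of phase dynamics to shape
  evolution, no level-set advection or reinitialization.
- The jet level-set machinery (tracking φ-derivatives for Hermite
  interpolation) is replaced by analytic signed distances, which the two
  static shapes provide exactly; field interpolation is tensor-product
  Lagrange.
- Re-extension injects an O(h⁴) per-step perturbation; on coarse grids
  this floors temporal self-convergence measurements (the order test runs
  at N = 33 where the floor is subdominant).
- The discrete noise satisfies conservation and σ-scaling exactly but
  fluctuation–dissipation balance only approximately, as inherent to the
  discretization.
- The energy functional is not provably non-increasing for the
  semi-implicit scheme; monotonic decay holds in practice at resolved
  interfaces and the reference time step, and is verified by test.
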