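# Methods

## Models

Three variants share the demographic core: forest trees recruit on
non-forest cover at rate `α` weighted by locally available seeds,
savanna trees recruit from saplings at the fire-suppressed rate `ω(G)`,
saplings appear on grass at rate `β` weighted by savanna-tree seeds, and
forest trees die at the fire-driven rate `φ(G)`.  Saplings and savanna
trees die at constant rates `μ = 0.1` and `ν = 0.05`.  The fire
responses are logistic in grass cover,

```
φ(G) = 0.1 + 0.8 / (1 + exp(-(G - 0.4)/0.05))     (increasing)
ω(G) = 0.9 - 0.5 / (1 + exp(-(G - 0.4)/0.01))     (decreasing)
```

reflecting the empirical ~40% flammable-cover threshold for fire spread;
Heaviside limits of both are available and are what the closed-form
stability arguments use (their derivative vanishes almost everywhere,
which is what removes the nonlocal fire term from every linearization).

The resource-limited variants multiply forest recruitment by
`1 − F/r`, a phenomenological cap `r ∈ (0, 1]` on forest cover standing
in for water/nutrient limitation; spatially the cap reads
`1 − (R∗F)/r` with a competition kernel `R`.  In the grass–forest
subsystem (`S = T = 0`) the simplex constraint `F = 1 − G` reduces the
dynamics to one scalar nonlocal equation for `G`.

All kernels are probability densities (unit mass, even).  Unit mass
makes nonspatial equilibria exact homogeneous steady states; evenness
keeps transforms real.  Built-in families carry closed-form transforms
(`exp(−σ²ξ²/2)` for the Gaussian); positive definiteness (nonnegative
transform) is what the necessary-condition argument needs and is checked
numerically for tabulated kernels.

## Linear stability

Stability of a homogeneous state is resolved per wavenumber: the scalar
model gives `λ_ξ = A ŵ + B R̂ + C Ĵ_F + D` (coefficients in the README);
the four-type models give a 4×4 matrix whose forest row decouples under
Heaviside responses, leaving the grass–forest relation plus a 3×3 block
handled by the Routh–Hurwitz criterion.  Two structural results are
enforced as property tests rather than assumed: (i) without resource
limitation, ODE-stable states never destabilize spatially, for *any*
admissible kernels; (ii) the all-grass state never destabilizes
spatially when the kernels are positive definite.

Wavenumber grids: heatmaps and onset bisection scan 4000 log-spaced
points on `(0.01, 200]` (by default), enough for `λ_ξ` to reach its
`ξ → ∞` limit `D` to ~1e−6; comparisons against discretized operators
use the box's integer modes instead.  Both conventions are exposed
because published heatmaps rarely say which one they used.

`turing_onset` tracks every ODE-stable interior branch through an
`α` scan by nearest-`Ḡ` matching (141 samples by default), bisects sign
changes of the per-branch dispersion maximum to 1e−4, and pools the
crossings.  On the standard slice (`r = 0.84`, `σ_W = 0.025`,
`σ_F = 0.1`, `σ_R = 0.15`) the two crossings sit on *different*
branches: the grass-dominated branch destabilizes at `α ≈ 4.344` just
before its own fold (`α ≈ 4.40`), while the forest-dominated branch —
spatially unstable from its birth fold at `α ≈ 3.85` — restabilizes at
`α ≈ 4.793`.

### The localized-competition slice

For `σ_R = 0.05` (competition more local than dispersal) the Turing
region in `(r, α)` is a small island at `r ≈ 0.74–0.80`; no instability
exists at `r = 0.84`.  The `fig5-bottom` preset therefore slices through
the middle of the island at `r = 0.77`, where the window closes at
`α ≈ 6.078`.  The slice value is a package choice: any `r` in the island
gives the same qualitative picture, with the restabilization point
moving by roughly ±0.5 across the island.

## Length-unit conventions

The model is scale invariant: rescaling space rescales all kernel widths
together.  Simulation presets keep the printed widths on the box
`[−π, π]` (so the `fig4` point `α = 2.15, r = 1, σ_R = 0.4` has unstable
integer modes 3–56, fastest ≈ 7).  Continuation presets instead read the
widths as fractions of a unit-length periodic domain (`[−1/2, 1/2]`,
256 points): with `σ_R = 0.15` this puts the critical wavenumber at
integer modes 2–3, which is what makes the coarse two- and three-bump
branches the relevant ones.  On the unit domain the resource kernel
(`σ_R = 0.15` of the domain length) is wide; discretization wraps three
periodic images and renormalizes to exactly unit discrete mass, so
homogeneous equilibria stay exact fixed points regardless of wrap error.

## Time integration

Explicit RK4 with spectral (FFT) convolutions.  The nonlocal operator is
bounded — there is no diffusive stiffness — so the step limit comes from
demographic rates and the sigmoid slopes; a crude estimate
(`≈ 2.5 / max rate`) triggers a warning only.  Defaults: `dt = 1e−3` for
conservation studies, `dt = 0.02` for pattern-formation runs (growth
rates are O(0.1)).  Cover fractions are clipped at zero when undershoot
stays below 1e−8 (recorded in the trajectory diagnostics); anything
larger aborts, since it signals a genuinely unstable step, and silent
clipping would mask it.  Pointwise simplex conservation over `T = 100`
four-type runs stays below 1e−8.

Mode growth rates are least-squares slopes of `log |amplitude|` while
the amplitude stays under 1e−3; they agree with `λ_ξ` to better than 2%
when the kernels are resolved by the grid.  For deliberately
under-resolved kernels (the `fig4` fire kernel has `σ_W = 0.01` against
a cell of 0.0245) the simulator's effective transform is the DFT symbol
of the sampled kernel, and consistency checks must use that symbol; the
package exposes the discretized kernels so tests can do exactly this.

## Continuation

The scalar steady-state problem on the 256-point periodic grid is dense
(kernel operators are full circulants), so Newton uses the exact dense
Jacobian and LU solves; converged residuals are below 1e−10.
Pseudo-arclength continuation uses a secant predictor and a bordered
corrector, with steps adapting between 1e−9 and 0.04.  Folds are
detected as sign changes of `dα/ds` and refined by a parabola through
the three neighbouring points (the quadratic vertex locates the fold to
~1e−5 given the step sizes used).  Stability per point comes from the
dense linearization; the translation eigenvalue of the periodic domain
(zero up to discretization, in practice < 1e−4) is excluded by dropping
the single eigenvalue nearest zero.  No phase condition is imposed: the
grid weakly pins the phase already, the bordered system stays well
conditioned in practice, and a fixed-phase row would conflict with the
asymmetric states described next.  (A phase-pinning option exists for
symmetric eigenmode-seeded branches.)

### Following the stable patterned branch

The symmetric two-bump state (obtained by time-stepping from a
`cos(2x)`-biased initial condition at `α = 4.5` and Newton-polishing) is
stable from its subcritical fold at `α ≈ 2.929` up to `α ≈ 5.5`, where
it sheds stability to an antisymmetric mode while its own branch
continues to a fold at `α ≈ 8.23`.  The attractor beyond 5.5 is a
nearby asymmetric (mixed two/three-bump) state.
`upper_fold_of_stable_branch` follows the *stable* patterned branch: it
continues upward, and when the branch acquires a positive
non-translation eigenvalue before folding it perturbs along the unstable
eigenvector, relaxes by time integration back onto the attractor, and
resumes continuation; the first genuine fold of the stable branch is at
`α ≈ 8.445`.  Branch endpoints connecting to the homogeneous branch meet
it at the bisected Turing onsets to ~1e−2.

## Synthetic inputs and what tests show

There are no external data; all inputs are parameter sets, and the
"synthetic data" of the test suite are seeded white-noise or single-mode
perturbations of homogeneous states plus randomly drawn kernel triples
(Gaussian/Laplace/uniform, widths 0.01–0.5).  These exercise the theory
on exactly the homogeneous, isotropic, periodic setting it assumes; they
say nothing about heterogeneous real landscapes (rainfall gradients,
topography, anisotropic wind dispersal), where the homogeneous-domain
analysis is only a local approximation.

## Numerical choices and limitations

* Equilibria: scalar model by dense sign-change bracketing (10⁴
  subintervals) + Brent; four-type models by damped Newton from a 12³
  simplex lattice, de-duplicated at 1e−6; closed-form quadratics per
  threshold side for Heaviside responses.  Roots at exactly a Heaviside
  threshold are rejected (derivative undefined).
* Hopf/saddle-node/transcritical flags in two-parameter scans are
  grid-resolution diagnostics (eigenvalue proximity, count changes);
  no normal-form coefficients are computed, so criticality of Hopf
  curves is not classified.
* Stability of spatially homogeneous *periodic orbits* is out of scope,
  as are homoclinic structures and two-parameter continuation of fold
  or Turing curves.
* Multi-bump branches beyond the coarse ones (snaking candidates) are
  reachable through the same API (seed other modes) but are not part of
  the reported results.
* Problem sizes of the reported runs: 141-point `α` tracking for onset
  bisection; 256-point continuation grids; 100×100 `(r, α)` cells and
  19 widths for the kernel-persistence scan; 1D pattern runs at
  `N = 256, T = 150`, 2D at `128², T = 150`.
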