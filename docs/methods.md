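# Methods

## The landscape model

Each vulval precursor cell (VPC) is a point **x**(t) = (x, y) moving in a
two-dimensional gradient-like flow assembled from the two generic
catastrophes of one- and two-parameter gradient systems:

* a **fold** (saddle-node) on the y-axis with normal form
  `f_fold(u, c) = -u² - c`, vertically offset by `M`.  For `c < 0` it
  carries an attractor at `(0, M + √(-c))` — the tertiary (non-vulval,
  default) fate — and a saddle at `(0, M - √(-c))`; at `c = 0` they merge
  and for `c > 0` the tertiary fate no longer exists.
* a **cusp** on the invariant line `y = 0` with normal form
  `f_cusp(x, a, b) = -4x³ - 2ax - b`.  Its discriminant `Δ = 8a³ + 27b²`
  organizes the vulval pair: for `Δ < 0` two attractors (primary at
  `x < 0`, secondary at `x > 0`) flank a saddle; for `Δ > 0` a single
  vulval attractor survives, on the side selected by the sign of `b`.

The merged field is

```
x' = τ [ H(-y) f_cusp(x, a, b) - (1 - H(-y)) x ]
y' = τ [ y f_fold(y - M, c) ]
```

with `H` a unit step and `τ > 0` a rate constant.  The step convention is
`H(u) = 1 for u ≥ 0`, so the cusp branch governs `y ≤ 0` and the plain
contraction `-x` governs `y > 0`; this is the only convention under which
the critical points listed above are exact equilibria of the merged field
(the alternative reading, cusp strictly below zero, leaves the fold pair
off-equilibrium).  The bifurcation set is exactly
`{c = 0} ∪ {Δ = 0}`: crossing the fold line changes the critical-point
count by two, and at least one vulval attractor exists for every parameter
value — a cell that has left the tertiary basin must commit to primary or
secondary ("binary flip").

### Smoothing the step

For SDE integration the step is replaced by a logistic of configurable
width `w` (default 1e-3 phase units).  A logistic centered exactly on
`y = 0` would evaluate to ½ on the invariant line and mix the `-x`
contraction into the cusp dynamics, displacing the vulval attractors by an
O(1) amount (e.g. ±1/√2 → ±1/2 for a = -1, b = 0).  The step is therefore
centered `√w` above the line: the offset vanishes with `w` while the step
value on the line tends to 1, so the smoothed equilibria converge to the
sharp-step closed forms as `w → 0` (verified by a root-bracketing test).
Geometry functions (`find_critical_points`, `classify_landscape`) always
use the sharp step.

## Signals and their mapping into the landscape

The control point is an affine image of the scaled signals,
`(a, b, c)ᵀ = m (s θ_E, l θ_N)ᵀ + q`, with `|m_ij| < 1` and `s, l > 0`.
The image plane `π_T: Aa + Bb + Cc = D` has `(A, B, C)` the 2×2 minors of
`m` and `D = Aq₁ + Bq₂ + Cq₃` (the sign of `D` follows from requiring the
zero-signal point `q` to lie on the plane).  The map must satisfy:
(i) the zero-signal origin is tristable, with the fold pair above the cusp
line (`M > √(-c₀)`) so the starting tertiary basin is well formed;
(ii) signals can drive the system out of the tristable region;
(iii)–(iv) the Notch-null profiles at twice and at wild-type EGF lie
outside the tristable region.  These four conditions form the indicator
factor of the prior.  Condition (ii) is implied by (iii); the public
checker nevertheless reports it independently on a 7×7 signal grid.

EGF rises in time as `σ(t) = (1 + tanh(H_E t + M_E))/2` on a competence
clock normalized to `t ∈ [0, 1]`, attenuated by `γ ≤ 1` per cell position
(`σ, γσ, γ²σ` for P6.p, P5.p, P4.p).  Notch production of a cell is
`L(x) = (1 + tanh(n₀ + n₁·x))/2` with `n₁ = (-‖n₁‖, 0)`, rising toward
the primary basin; a cell receives paracrine Notch from both neighbors
plus `α` times its own production, attenuated by receptor downregulation
`(1 - l_d L)`.  Only P4–6.p are modeled: P6.p's outer neighbor mirrors
P5.p (symmetry about the anchor cell) and P4.p's outer neighbor
contributes nothing (P3.p is tertiary-fated).  Anchor-cell ablation
freezes EGF production at the ablation time and decays both received
signals at rate λ (a single fitted decay serves both channels).  The six
ablation stages are ordered but not timed in the source data; they sit at
evenly spaced defaults t = 0, 1/6, …, 5/6.

Perturbation lines are condition records: multiplicative EGF dose
(2 anchor cells = ×2, half ligand = ×0.5, overexpression strains at their
measured fold levels), a multiplicative factor on received Notch
(1 wild type, 0 null, 0.5 half receptor dose), an additive ectopic-Notch
constant, and receptor mosaics (zero EGF reception in P5.p).  Three
perturbation strengths are not measured and are fitted one-dimensionally
(see below); the JU1100 overexpression level is a fitted nuisance
parameter appended to the manifest during training fits.

## Simulation and fate calling

Cells start exactly at the zero-signal tertiary attractor
`(0, M + √(-q₃))` (equivalent developmental potential, no initial
spread) and evolve by Euler–Maruyama with additive isotropic noise
`σ_dif` on both coordinates, default `dt = 1e-3` on the unit competence
clock.  First-order convergence is verified by Richardson comparison, and
fate proportions are stable under dt halving to within binomial error.
At `t_end` the signals are cut and each cell relaxes noise-free under the
zero-signal landscape; the fate is the attractor reached (within radius
1e-3), and a trajectory that reaches none within the step budget — or
leaves the |x|,|y| ≤ 50 box — is *unassigned*.  Unassigned outcomes are
penalized by the fitting distance rather than resampled, so pathological
parameter regions are disfavored instead of hidden.

The relaxation exploits the merged field's structure for exact early
decisions: above the top saddle the y-flow is monotone to the tertiary
attractor, and once a trajectory is inside the saturated cusp zone the
flow is one-dimensional in x, so the side of the middle cusp root decides
the basin.  States within the convergence radius of either saddle are
never assigned geometrically; they keep integrating and become unassigned
on budget exhaustion, preserving the no-arbitrary-assignment rule.

Isolated-cell pulse protocols script the received signals directly
(constant levels over half-open intervals, no Notch coupling).  A pulse's
effect is relative to the fitted kinetics: how far a cell travels during a
pulse of given length depends on the particle's rate constant and EGF
time course, so outcome compositions under a fixed schedule are
particle-dependent, while the irreversibility of the tertiary exit is
structural (the y-flow below the top saddle cannot re-cross it for any
signal value).

## Fitting: ABC SMC with an OLCM kernel

The distance between an observed condition set and a simulation is the L1
mismatch of fate proportions plus the total unassigned proportion,
averaged over conditions; cells missing from a record (ablation rows lack
P4.p) are skipped in both terms.  The sampler: generation 1 rejection-
samples the constrained prior at threshold ε₁; each later generation's
threshold is the ceil(0.3 n)-th smallest of the previous accepted
distances (strictly decreasing, with ties broken by an epsilon nudge);
parents are resampled by weight and perturbed with a Gaussian kernel whose
covariance is the Optimal Local Covariance Matrix — the weighted scatter,
about the parent, of the previous particles already satisfying the next
threshold — plus a 1e-8 diagonal jitter; weights follow
`π(θ') / Σ_j w_j K_j(θ')`.  Priors are flat on finite supports.  The
supports are this package's own reconstructions (the original analysis
did not print its exact supports): matrix entries on (-1, 1) as
the model requires, offsets `q₁, q₃` on (-3, 0) (negative at the origin by
the tristability constraint), scalings on (0.1, 10), `γ` on (0.01, 1),
noise on (0, 0.5), rate and decay constants sized for the unit clock.

Proposals outside the prior support or violating the constraint indicator
are rejected before simulation; the stagnation budget therefore counts
simulator evaluations, with a generous cap on raw proposals.

### Desk-scale sizes

The full-scale study design (2×10⁴ particles × 14 generations, each
evaluation simulating ten conditions) is a cluster job.  The package's
acceptance paths use N = 256 particles, up to 12 generations, 16
stochastic replicates per condition per distance evaluation, and ε₁ = 4
(the command-line `fit` accepts any sizes).  At this
population size the importance weights are noticeably heavier-tailed than
at full scale: the effective sample size (ESS) per generation is reported
and can collapse to a handful of particles in later generations — a known
small-N pathology of the `π/Σ wK` weights in a ~23-dimensional space.  The
threshold schedule and kernel construction are unchanged, and point
summaries (e.g. the posterior mean of γ) use the final generation,
matching the usual reporting convention; *interval* summaries, however,
are taken from the last generation whose ESS is at least 10, because
weighted quantiles of a weight-degenerate population have zero width and
no coverage.  A deterministic evaluation budget (9,000 simulator calls by
default in the acceptance paths) bounds each run; if it is exhausted the
run stops cleanly with the completed generations.  Parameter-recovery
checks run at N = 128 with 6 generations on synthetic observations.

Identifiability caveat: at these budgets the sampler follows essentially
one particle lineage, and at desk-scale replicate counts the training
distance can admit more than one local mode in parameters such as the EGF
attenuation γ; a budget-capped run settles in a seed-dependent mode, and
resolving the posterior across modes requires population sizes closer to
the full-scale design.  The acceptance outputs report the capped run's
posterior mean as computed, with the population size used.

### One-dimensional perturbation-strength fits

Conditional on a fitted particle, each unmeasured perturbation strength is
fitted by a grid scan (with one refinement pass) of the pattern distance
over its own validation rows: the Notch-reduction factor on the
reduced-Notch strains, the ectopic-Notch additive constant on the
strongest ectopic × overexpression cross, and the EGF-hypomorph factor on
the hypomorph strain.  The published constants (0.4, 0.12, 0.36) were
obtained conditional on a full-scale posterior particle; at desk scale
these one-dimensional fits inherit the particle's imperfections, and the
package's tests allow ±0.15 absolute around the published values.

## What the synthetic-data generator emulates

`generate_synthetic_observations` replaces a condition table's observed
proportions with simulator output from a known parameter vector
(unassigned outcomes renormalized away), enabling closed-loop recovery
tests.  It reproduces the *structure* of the experimental tables —
fate proportions per cell per condition, missing cells in ablation rows —
but not features of real data such as finite animal counts per strain
(published proportions come from tens of animals, not the generator's
exact binomial sampling), strain-background effects, or unmodeled cells
(P3.p, and the averaging of P5/7.p and P4/8.p pairs).  Passing recovery
tests therefore demonstrates the identifiability of the inference
machinery under the model's own assumptions, not the correctness of those
assumptions for the worm.

## Numerical choices and degenerate inputs

* Stratum tolerances: |Δ| and |c| within 1e-9 are treated as on-stratum;
  degenerate critical points are returned flagged, never dropped.
* Fold points with `y ≤ 0` are genuine equilibria of the merged field only
  when `b = 0`; `find_critical_points` includes them only in that case.
* `classify_landscape` with `Δ > 0` and `b = 0` (forcing `a > 0`, a single
  attractor at `x = 0`) reports a degenerate vulval state: the surviving
  attractor is on neither the primary nor the secondary side.
* Fate assignment never breaks ties: a trajectory that converges to no
  attractor (saddle starts, exhausted budgets) is unassigned.
* Reproducibility: every stochastic component (prior draws, kernel
  perturbations, simulator replicates) derives its stream from
  (seed, generation, proposal index) via `SeedSequence`, making runs
  independent of worker count and bitwise repeatable.

## Known limitations

* The affine signal map cannot reproduce the EGF-hypomorph details that
  the source analysis also failed to capture (a nonlinear map in the
  low-EGF region would be required).
* The EGF time course is the default sigmoid; the slight modification the
  original fit suggested is supplementary-only and is represented here by
  the pluggable `timecourse` hook rather than a specific form.
* Ablation-stage times are fixed evenly spaced constants, not fitted.
* At desk-scale population sizes the ABC posterior is a coarse
  approximation; quantities reported by `scripts/acceptance.py` are
  labeled with the problem sizes used.
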