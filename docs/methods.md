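# Methods

## The models

A substrate A with n ordered phosphosites is converted sequentially and
distributively between phosphoforms S_0 … S_n by a kinase (upward) and a
phosphatase (downward).  Four families are built as mass-action reaction
networks:

* **MA** — full Michaelis–Menten mechanisms: each enzymatic step is
  bind/unbind/catalyze (`K + S_i ⇌ K·S_i → K + S_{i+1}`, rates a_i, d_i,
  k_i; phosphatase analogously with a′, d′, k′).  Free enzyme is
  distinguished from total enzyme, so sequestration of enzyme in complexes
  is explicit.  The Michaelis constant of a step is K_M = (d + k)/a.
* **LR** — lumped linear rates: each step is a first-order conversion with
  effective constant b_i·K_tot (phosphorylation) or c_{i+1}·P_tot
  (dephosphorylation).  This is the K_M → ∞ limit of MA at fixed
  b = k_cat/K_M.

With a scaffold (S families), every phosphoform binds a scaffold protein B
reversibly (`S_i + B ⇌ S_i:B`, rates α_i, β_i, dissociation constant
Kd_i = β_i/α_i).  Phosphorylation acts by default only on scaffold-bound
substrate; dephosphorylation acts both on and off the scaffold (same
phosphatase constants in both compartments, configurable to off-only or
on-only).  The kinase binds bound substrate directly from solution, and an
enzyme–substrate complex neither binds nor releases the scaffold; scaffold
exchange happens only for uncomplexed substrate.  The scalar output is the
total fully phosphorylated substrate: S_n plus its scaffold-bound form plus
any enzyme complexes carrying phosphoform n.

Units package-wide: concentrations in µM, time in seconds; first-order
constants s⁻¹, second-order µM⁻¹s⁻¹.

## Steady states

Every steady state of an MA model satisfies the complex-slaving relations
`[E·S] = [E][S]/K_M`, which makes all substrate-containing species linear
functions of the free-enzyme/free-scaffold concentrations.  The problem
therefore reduces to:

* **MA with scaffold** — three unknowns (free K, free P, free B).  For a
  fixed triple, the substrate ladder (free and bound phosphoforms coupled
  by effective first-order conversions and binding) has a unique positive
  steady state, computed by an exact backward recursion in log space
  (overflow-proof over the ≥12 orders of magnitude the random rates span);
  the substrate total A_tot fixes the scale.  The remaining K_tot, P_tot,
  B_tot conservation mismatches are the residuals of a 3-dimensional root
  problem solved by damped Newton iteration (log coordinates,
  forward-difference Jacobian, step-halving damping, relative residual
  tolerance 1e-10) from a deterministic log-grid of starts spanning
  (1e-6·total, total) per coordinate plus seeded random starts.
* **MA without scaffold** — two unknowns (K, P); the free chain has the
  closed-form birth–death solution.
* **LR with scaffold** — one unknown, the free scaffold B ∈ (0, B_tot]:
  the substrate subsystem is solved exactly for each B and all roots of the
  scaffold conservation residual g(B) are found by a 1000-point log-grid
  bracket scan refined by bisection.
* **LR without scaffold** — closed form,
  S_{i+1}/S_i = b_i K_tot/(c_{i+1} P_tot).

In a dose sweep, every root found anywhere along the K_tot grid is re-used
as an additional Newton start at every other grid point (a cheap
continuation), so a branch is only lost if no start anywhere in the sweep
lands on it.  Converged roots are clustered in the reduced coordinates,
lifted to full species vectors, and deduplicated at relative L∞ 1e-6.

The default Newton protocol (`SolverOptions()`) uses a 5×5×5 grid plus 25
random starts at every dose.  Screens use a validated cheaper profile
(`FAST_SCREEN_OPTIONS`: 3×3×3 + 5 starts, the full multistart at every
second dose, warm starts covering the rest, and the whole Newton solve
batched across chunks of 25 parameter sets): on pilot batches of 40–80
parameter sets per regime it returned bit-identical bistability calls to
the heavier protocols (including the 125+25-start default) at a fraction
of the cost, so a 500-set five-site cell completes in about two minutes on
one CPU.

**Stability.**  The dynamics preserve the stoichiometric compatibility
class x₀ + Im(N), and the Jacobian J maps Im(N) into itself.  Stability is
decided by the eigenvalues of Qᵀ J Q, where Q is an orthonormal basis of
Im(N): this reduced spectrum carries no structural zero modes, so no
threshold tied to the largest eigenvalue is needed.  That matters here
because the random-rate spectra legitimately span >10 orders of magnitude;
a rule of the form |Re λ| < ε·max|λ| mislabels genuinely stable slow modes
as borderline precisely in the high-K_M regime.  A state is stable iff
every reduced eigenvalue has negative real part; states with a vanishing
real part (|Re λ| < 1e-12·max|λ_red|) are conservatively labeled unstable.
The full spectrum is also reported, and its n_laws smallest-magnitude
eigenvalues are checked to be structural zeros (≤ 1e-7·max|λ|).

An independent oracle, `integrate_to_steady_state`, integrates the full
stiff ODE system (BDF, analytic Jacobian, rtol 1e-8) over geometrically
growing time windows until max|dx/dt|/max(x) < 1e-9.  Once a window ends
inside an attractor's quadratic basin (rate < 1e-4), the endpoint is
sharpened by a full-dimension damped Newton step on the stoichiometric
class; the correction is accepted only if it moves the state by less than
1% — the choice of attractor is therefore made entirely by the
integration, and the polish merely avoids grinding a stiff integrator
against a fixed point.  The oracle is used throughout the tests to confirm
that solver states are exactly the attractors of the dynamics.

## Randomized screening

Every rate constant is log-uniform over 1e-3..1e3 (s⁻¹ or µM⁻¹s⁻¹) and
every total protein concentration log-uniform over 1..10 µM.  Three
restrictions define the screening conditions: B_tot ≤ A_tot (enforced by
resampling B_tot only, preserving the substrate marginal); scaffold
dissociation constants low for partial phosphoforms (Kd_i log-uniform in
1e-3..1 µM for i < n) and high for the full form (Kd_n in 10..1e3 µM); and
an optional Michaelis-constant bin — each (a, d, k) triple is redrawn until
its K_M lies in the requested decade.  Because triples are independent,
per-triple redrawing produces exactly the same conditional distribution as
rejecting whole parameter sets, at acceptance rates usable for n = 5
(whole-set rejection would accept ~1e-8 of draws); the equivalence is
verified by a two-sample test in the suite.

A parameter set is **bistable** when, at some point of a 50-point
logarithmic K_tot grid (default 1e-3..1e3 µM), at least two stable steady
states coexist whose outputs differ at least 5-fold (the smaller output
floored at 1e-12·A_tot).  Screens report the bistable percentage of 500
sets per cell with its binomial standard error 100·√(p(1−p)/n).  Solver
failures (no Newton start converged at a dose point) count as monostable
at that point and are logged — a bias against, never for, bistability.

## Choices where the design was open

* **Concentration ranges.**  The study conditions state rate ranges and a
  1..10 µM range for total protein concentrations; the package samples
  A_tot, B_tot and P_tot from that range (each configurable).  K_tot is not
  sampled: it is the dose variable.
* **Kd restriction form.**  The phosphostate dependence of scaffold binding
  is implemented as explicit log-uniform Kd ranges (policy knobs), the
  exact original cutoffs being unavailable; α is drawn from the rate range
  and β = α·Kd.
* **Fold-ratio denominator.**  The ratio compares the highest and lowest
  stable output at the *same* K_tot, matching the dose-response definition
  of the fold ratio; a variant comparing across the whole sweep would only
  be looser.
* **Same phosphatase constants on and off scaffold** when dephosphorylation
  acts in both compartments ("equally on and off").
* **LR↔MA twins.**  For the convergence analysis the MA twin of an LR set
  fixes k_cat/K_M to the lumped constant, scales K_M = σ·A_tot, and sets
  d = k_cat (so d > 0 holds for every σ).

## What the generator emulates — and what it does not

The generator reproduces the randomized-screen conditions: independent
log-uniform kinetics over six orders of magnitude, decade-binned Michaelis
constants, limited scaffold, phosphostate-dependent binding.  It does not
emulate features of real signaling systems such as correlated rate
constants within an enzyme family, processive phosphorylation, enzyme
sharing across tiers, membrane localization, or molecular noise.  Passing
screens therefore demonstrate properties of the model class under the
stated distributions — e.g. that scaffolds enlarge the bistable parameter
mass at high K_M — not quantitative predictions for any particular
pathway.

## Numerical edge cases

* The log-space ladder recursion is cancellation-free (all summands
  positive) and immune to overflow; the dense null-space fallback used by
  non-standard topologies (e.g. phosphorylation both on and off scaffold)
  operates in linear space and is only used where rates are moderate.
* A singular Newton iterate receives a tiny Tikhonov shift
  (1e-13·‖J‖); a start that cannot reduce its residual within 30 halvings
  is dropped (other starts cover its root).
* Borderline eigenvalues are labeled unstable, biasing *against* the
  headline bistability counts.
* For LR-S, a vanishing binding rate (α → 0) makes g(B) root-finding
  approach its B = B_tot endpoint smoothly; the scan grid includes the
  endpoint.

## Problem sizes used in the checks

Unit and property tests run at n ≤ 5 with tens to hundreds of random
parameter sets; the acceptance screens use 500 sets per cell (the tables'
own sample size) with the validated fast solver profile, and the
solver-vs-integration equivalence check uses 100 sets per family × 20
random initial conditions at n = 2.

## Known limitations

* Steady-state enumeration is numerical; completeness at any single dose
  rests on multi-start coverage plus cross-dose warm starts, not on an
  algebraic certificate.  (For LR-S the 1-D bracket scan is exhaustive up
  to grid resolution.)
* The bistable K_tot interval is resolved only to the dose-grid spacing;
  there is no fold-point refinement or arc-length continuation.
* Deficiency-based conclusions are verified numerically (zero bistable
  draws over the provably monostable topologies), not re-proved
  symbolically.
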