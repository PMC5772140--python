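# Methods

## The stochastic model

Nodes of an undirected, static contact network are susceptible, infected or
recovered. When a node becomes infected it receives an *age of infection*
a = 0. Two independent delay distributions drive everything: τ(a), the
density of the time from infection to a transmission attempt along one edge,
and q(a), the density of the infectious period. A transmission attempt at
age a succeeds only if the node has not yet recovered, so the density of the
*first effective attempt* on an edge is f(a) = τ(a) ξ_q(a), with
ξ_q(a) = P(period > a) the recovery survival function. Symmetrically
g(a) = q(a) ξ_τ(a) is the density of recovering at age a without ever having
attempted transmission on that edge; under independence ∫(f + g) da = 1.
Recovery confers permanent immunity. A fraction z of nodes is initially
susceptible; the remaining 1 − z are infected at t = 0 with age 0 ("fresh
cohort").

Networks are configuration-model (CM) graphs: degrees drawn i.i.d. from a
prescribed distribution p_k, stubs matched uniformly at random. The network
enters the mean-field equations only through the generating functions
G₀(x) = Σ p_k x^k, G₁(x) = Σ p_k k x^(k−1)/⟨k⟩ (excess degree) and
G₂ = G₁′. The mean excess degree is G₁′(1) = Σ p_k k(k−1)/⟨k⟩ — note this
equals G₂(1), not G₂′(1).

## Mean-field models and why there are two of them

The **message-passing model** works with H₁(t), the probability that a
random neighbour of a cavity-state test node (one that can be infected but
cannot transmit) has not attempted transmission to it by time t:

    H₁(t) = 1 − ∫₀ᵗ f(a) [1 − z G₁(H₁(t − a))] da,   H₁(0) = 1,
    S = z G₀(H₁),   R(t) = ∫₀ᵗ q(a) [1 − S(t − a)] da,   I = 1 − S − R.

The **edge-based compartmental model** tracks the same object, called Θ(t),
through age-structured densities: φ_I(t, a) for infected neighbours of age a
that have not transmitted to the test node, and i(t, a) for infected nodes
of age a, with transport equations (∂_t + ∂_a)φ_I = −(ζ + ρ)φ_I and
(∂_t + ∂_a)i = −ρ i in the hazards ζ = τ/ξ_τ, ρ = q/ξ_q, boundary conditions
φ_I(t,0) = (1−z)δ(t) + z G₂(Θ) ∫ζφ_I da and i(t,0) = (1−z)δ(t) +
⟨k⟩ z G₁(Θ) ∫ζφ_I da, and dΘ/dt = −∫ζφ_I da.

The two formulations are provably equivalent (substituting the integrated
transport solution into the Θ equation reproduces the H₁ equation, since
ζ ξ_τ ξ_q = f). Both are exact in the limit of the infinite CM ensemble,
where the graph is locally tree-like. On a *finite tree* the per-edge
version of the message equations is exact for that very network, which
gives the package its sharpest validation oracle.

From either model the final size follows as r_∞ = 1 − G₀(Θ_∞) with
Θ_∞ = 1 − T̃ + T̃ G₁(Θ_∞) and T̃ = ∫₀^∞ f(a) da the transmissibility; the
ratio T̃ × (mean excess degree) plays the role of a reproduction number
(outbreak possible iff > 1).

## Pairwise hierarchy

For Poisson transmission (τ exponential with rate β) the MP model can be
rewritten in population-level counts: [S] = zN G₀(H₁), the S–I edge count
[SI], and the convolution [I](t) = β ∫₀ᵗ [SI](t−a) ξ_q(a) da + N(1−z)ξ_q(t).
The [SI] equation carries a memory integral against q(a)e^{−βa}. The system
is closed — no triple-closure approximation — because H₁ is retained.
Specialisations implemented: regular networks (H₁ eliminated via
H₁^{k−1} = exp(−β∫ (k−1)/k · [SI]/[S]), introducing [SS]); exponential
recovery (all memory collapses, plain ODEs); fixed period σ (memory
collapses to lag-σ terms; the initial cohort recovers as an impulse at
t = σ). [I] uses the integral form throughout: it avoids point evaluations
of q, which would be meaningless at atoms.

The pairwise solvers require exponential transmission and raise
`UnsupportedModelError` otherwise; this is structural (the
re-parametrisation depends on the memoryless property), not a numerical
limitation.

## Numerical choices

- **Atoms are first-class.** Fixed periods are point masses, never narrow
  densities. Atoms enter integrals by direct evaluation: in f as lagged
  point terms, in R(t) as lagged jumps, in the pairwise systems as
  impulses and exact lag terms (the lag must sit on the grid; enforced).
- **Volterra solver (MP):** product-trapezoidal discretisation. Per-cell
  kernel masses ∫_cell f(a) da are precomputed by composite Simpson with
  atom-aware one-sided survival values at cell ends (a survival jump on a
  cell boundary is integrated exactly from within each cell); the unknown
  is piecewise linear. The implicit endpoint is resolved by damped fixed
  point (tolerance 1e−10, ≤ 50 iterations). The same machinery solves the
  per-edge tree equations, one message per directed edge.
- **EBCM solver:** time and age share one step h, so characteristics are
  exact grid shifts with no interpolation. Cell decay factors are exact
  survival-function ratios (the integrated hazard in closed form), so the
  stored density factorises as i(t, a) = ξ_q(a) i(t−a, 0) to machine
  precision. The initial-cohort Dirac masses are explicit atoms with
  analytically decayed weights (1−z)ξ_τ(t)ξ_q(t) and (1−z)ξ_q(t). Θ is
  advanced by the trapezoidal rule with the implicit force-of-infection
  resolved by fixed point (tolerance 1e−12). The transmission distribution
  must have a density — its hazard enters the force integral pointwise —
  so transmission atoms are rejected (the MP solver covers them); recovery
  atoms are fully supported. Φ_R is defined by subtraction and monitored
  for non-negativity rather than enforced.
- **Pairwise solvers:** Heun's method on a fixed grid (the Markovian ODE
  variants use classical 4th-order Runge–Kutta); history integrals are
  product-trapezoidal on the same grid; the regular-network memory factor
  is maintained from a running integral so kernels never need e^{+c}
  recomputation over the whole history.
- **Quadrature:** transmissibility and kernel-mass checks use adaptive
  quadrature (absolute tolerance 1e−10) with breakpoints at atom locations
  and the improper limit capped where ξ_τ ξ_q < 1e−12.
- **Ties and degenerate inputs:** a transmission and a recovery scheduled
  at the same instant resolve in favour of recovery (d < r strictly),
  matching the f-kernel convention; z = 1 yields frozen dynamics in every
  solver; a cyclic network is rejected by the per-edge tree solver unless
  an explicit approximation flag is passed.

## Stochastic simulation

`simulate_rejection` (Poisson transmission, arbitrary recovery): recovery
times are drawn when a node is infected; the next putative transmission is
exponential with rate β × (#S–I edges); if a scheduled recovery comes first
the transmission is rejected. Uniform S–I edge choice uses rejection
sampling on the infected endpoint (bounded by the maximum degree), which is
exact and O(1) amortised. `simulate_event_driven` (arbitrary τ, q): on
infection, draw r ~ q and per-neighbour d ~ τ, schedule an attempt iff
d < r; attempts on non-susceptible targets are no-ops. Its per-edge
first-attempt law is exactly f(a), the mean-field kernel, and with
exponential τ it is distributionally identical to the rejection method
(verified by a final-size chi-square test). One master seed; run r uses
`default_rng([master, r])`, so ensembles are reproducible and
embarrassingly parallel. Initial conditions: an explicit node set, a count
(uniform without replacement), or a per-node Bernoulli fraction — the last
matches the mean-field independence convention and is the default for
validation. The burn-in protocol (`align_at_threshold`) instead starts from
a single seed, resets the clock when prevalence first reaches a threshold,
and reports the susceptible fraction at reset for the mean-field z; runs
that die out are flagged for discarding.

## The validation experiment

The reference experiment compares mean-field prevalence with event-driven
ensembles on truncated power-law networks (exponent 2.5, degrees 3–60,
N = 1000), Poisson transmission β = 0.3, and three infectious-period laws
of equal mean 2: exponential(γ = 0.5), truncated normal(2, 0.75), fixed 2.
Conditions chosen once: fresh-cohort seeding with z = 0.99, 200 runs, a
fresh CM network per run (the mean-field target is the CM *ensemble*),
horizon T = 15, solver step h = 0.01, output grid 0.1. The truncated
normal restricts the normal(2, 0.75) to a ≥ 0 and renormalises (≈0.4% of
mass); its mean is 2.009, treated as "mean 2" at the 1% level.

What passing shows — and does not. At N = 1000 the ensemble mean prevalence
sits a few percent below the mean-field curve near the peak; this gap is a
finite-size effect and shrinks as N grows (peak gap ≈ 0.014 → 0.005 → 0.001
at N = 1000 → 4000 → 16000 in the package's own measurements). The
acceptance check therefore asserts that the mean-field curve lies inside
the band covering ~95% of individual realisations (mean ± 1.96 sd) at
≥ 90% of grid points — the deterministic curve is statistically a typical
realisation — not inside the far narrower confidence band of the ensemble
mean (mean ± 1.96 se), which no exact implementation could satisfy at this
N. Both coverages are reported by the acceptance script. Prevalence is a
multiple of 1/N, so both bands carry a half-node (0.5/N) resolution floor;
without it the band degenerates to a point after the epidemic burns out.
The ensembles also confirm the variance effect: peak prevalence orders
exponential < normal < fixed with non-overlapping confidence intervals of
the mean peaks.

The synthetic generators emulate idealised CM networks and i.i.d. delays.
They do not model degree–degree correlations, clustering, household
structure, dynamic contacts, or correlated transmission/recovery, so
agreement here says nothing about those features of real contact data.

## Known limitations

- The erased configuration model discards self-loops and multi-edges
  (< 2% of edges at the sizes used), slightly thinning high-degree nodes.
- The EBCM solver rejects transmission-delay atoms; use MP for those.
- The pairwise hierarchy requires Poisson transmission by construction.
- Per-edge messages are exact only on forests; on cyclic graphs they are a
  (typically upper-bounding) approximation behind an explicit flag.
- All mean-field claims are asymptotic in N; at N ≈ 1000 expect few-percent
  deviations near the epidemic peak.
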