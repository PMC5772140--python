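# netsir

Mean-field and stochastic models for **SIR epidemics on configuration-model
networks with general (non-Markovian) transmission and recovery processes**.

Classical network epidemic models assume memoryless (exponential) waiting
times. Real diseases do not: infectious periods are usually peaked around a
well-defined mean, and the *shape* of that distribution changes the epidemic
even at fixed mean. `netsir` implements, for independent transmission-delay
density τ(a) and infectious-period density q(a) (a = age of infection), four
mutually consistent views of the same stochastic epidemic:

- **Message passing (MP)** — the average message H₁(t), the probability that
  a neighbour of a cavity-state test node has not attempted transmission by
  time t, solves the Volterra equation
  H₁(t) = 1 − ∫₀ᵗ f(a)[1 − z G₁(H₁(t−a))] da with f(a) = τ(a) ξ_q(a),
  where ξ_q is the recovery survival function and G₁ the excess-degree
  generating function; then S = z G₀(H₁), R(t) = ∫₀ᵗ q(a)[1 − S(t−a)] da.
  Per-edge messages on finite trees reproduce the stochastic epidemic
  *exactly*.
- **Edge-based compartmental model (EBCM)** — an age-structured formulation
  in Θ(t) and densities φ_I(t, a), i(t, a) driven by the hazard functions
  ζ = τ/ξ_τ and ρ = q/ξ_q, solved by the method of characteristics. MP and
  EBCM are equivalent in the continuum; the package solves them by entirely
  different discretisations and verifies the equivalence numerically.
- **Pairwise hierarchy** — for Poisson transmission (rate β) the MP model is
  re-parametrised into count-level systems in [S], [I], [SI] (and [SS] on
  regular networks) that close without moment-closure approximations, and
  specialise to the classical pairwise, Markovian, and fixed-period
  delay-differential models.
- **Stochastic simulation** — a rejection-method sampler (Poisson
  transmission, arbitrary recovery) and an event-driven sampler (arbitrary
  τ and q) that are statistically exact, with ensemble averaging and a
  burn-in/clock-reset protocol.

Analytics: transmissibility T̃ = ∫ f(a) da, the epidemic-threshold ratio
T̃ × (mean excess degree), and the final size r_∞ = 1 − G₀(Θ_∞) with
Θ_∞ = 1 − T̃ + T̃ G₁(Θ_∞).

Built-in degree families: regular, Poisson, truncated power law, empirical.
Built-in delay laws: exponential, fixed duration (a true point mass — every
solver handles atoms exactly), truncated normal, gamma, Weibull, empirical.

## Worked example

```python
from netsir import (DiseaseModel, GeneratingFunctionSet, equivalence_report,
                    final_size, make_degree_distribution, parse_delay_spec,
                    solve_ebcm, solve_mp, transmissibility)

gfs = GeneratingFunctionSet(
    make_degree_distribution("powerlaw_truncated", exponent=2.5, kmin=3, kmax=60))
model = DiseaseModel(parse_delay_spec("exp:0.3"),   # transmission rate 0.3
                     parse_delay_spec("fixed:2"))   # infectious period = 2

print(transmissibility(model))          # 0.45118836390597356
print(final_size(gfs, model)[1])        # 0.874220074920873

mp = solve_mp(gfs, model, z=0.99, T=15.0, h=0.01)
ebcm, _ = solve_ebcm(gfs, model, z=0.99, T=15.0, h=0.01)
print(mp.peak())                        # (2.91, 0.6211662829944042)
print(equivalence_report(mp, ebcm)["I"])  # 3.2079972264509315e-05
```

The transmissibility 1 − e^(−0.6) ≈ 0.451 is the probability an infected
node transmits across an edge before its fixed period ends; 87.4% of the
population is eventually infected; prevalence peaks at 62% at t ≈ 2.9; and
the two independently discretised mean-field models agree to 3×10⁻⁵.

The `examples/` directory contains one short script per capability
(analytics, mean-field models, pairwise hierarchy, tree exactness,
stochastic validation). A thin CLI wraps the same functions:

```bash
netsir finalsize --degree regular:3 --transmission exp:1.5 --recovery exp:0.5
netsir compare --degree powerlaw:2.5,3,60 --recovery fixed:2 --out out/
```

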