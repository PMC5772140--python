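"""The two general mean-field models, solved side by side.

The message-passing model is a Volterra integral equation in the average
message H1(t); the edge-based compartmental model is an age-structured
transport system in Theta(t) and the infected-neighbour density.  They are
equivalent in the continuum, so their numerically independent solutions
must agree to discretisation accuracy — shown here for an exponential and
a fixed infectious period (both mean 2).
"""

from netsir import (DiseaseModel, GeneratingFunctionSet, equivalence_report,
                    make_degree_distribution, parse_delay_spec, solve_ebcm,
                    solve_mp)

gfs = GeneratingFunctionSet(
    make_degree_distribution("powerlaw_truncated", exponent=2.5, kmin=3, kmax=60))

for label, q_spec in [("exponential(0.5)", "exp:0.5"), ("fixed sigma=2", "fixed:2")]:
    model = DiseaseModel(parse_delay_spec("exp:0.3"), parse_delay_spec(q_spec))
    mp = solve_mp(gfs, model, z=0.99, T=15.0, h=0.01)
    ebcm, _ = solve_ebcm(gfs, model, z=0.99, T=15.0, h=0.01, keep_densities=False)
    gaps = equivalence_report(mp, ebcm)
    t_peak, peak = mp.peak()
    print(f"recovery {label}:")
    print(f"  prevalence peak {peak:.4f} at t = {t_peak:.2f}; final R = {mp.R[-1]:.4f}")
    print(f"  MP vs EBCM sup-norm gaps: "
          + ", ".join(f"{k}={gaps[k]:.2e}" for k in ("message", "S", "I", "R")))
print("(gaps of order 1e-5 at h=0.01: the models are numerically equivalent)")
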