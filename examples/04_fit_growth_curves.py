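"""Fit the two growth laws and invert to minimum cohort-size requirements.

Fits N = a*X^b (log-log least squares) to the mean significant-gene
count against cohort size and against events number, and a logistic CDF
F(x) = 1/(1+exp(-(x-mu)/s)) to the probability of at least one hit.
The logistic inverse gives the smallest cohort achieving a 90% discovery
probability; the 100% requirement is read off empirically as the
smallest size from which every replicate succeeded.
"""

from progsat import (
    build_size_grid,
    expected_events,
    fit_logistic_cdf,
    fit_power_law,
    make_fixture,
    run_saturation,
    size_for_probability,
    summarize,
)

cohort, _ = make_fixture("stageII-like", seed=0)
grid = build_size_grid(cohort.n_samples, 0.10, 0.95, 8)
records = run_saturation(cohort, grid, n_reps=50, seed=0)
s = summarize(records)

pl = fit_power_law(s["size"].to_numpy(float), s["mean_significant"].to_numpy(float))
print(f"count vs size:   N = {pl.a:.4g} * X^{pl.b:.3f}  (R^2 = {pl.r_squared:.4f})")
pe = fit_power_law(s["mean_events"].to_numpy(float), s["mean_significant"].to_numpy(float))
print(f"count vs events: N = {pe.a:.4g} * X^{pe.b:.3f}  (R^2 = {pe.r_squared:.4f})")

lf = fit_logistic_cdf(s["size"].to_numpy(float), s["prob_ge1"].to_numpy(float))
print(f"logistic:        mu = {lf.mu:.1f} samples, s = {lf.s:.1f}")

n90 = size_for_probability(lf, records, 0.9)
n100 = size_for_probability(lf, records, 1.0)
print(f"\nminimum size for 90% discovery probability:  {n90}")
print(f"minimum size for 100% (empirical, all replicates succeed): {n100}")
if n100 is not None:
    ev = expected_events(n100, cohort.n_samples, cohort.n_events)
    print(f"which corresponds to about {ev} outcome events")
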