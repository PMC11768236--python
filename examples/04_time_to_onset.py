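"""Weibull time-to-onset profiling on a synthetic cohort.

Simulates a cohort whose onset delays are drawn from Weibull(scale=100 d,
shape=0.9), extracts time-to-onset for the exposed reports (one-year
window, input errors and missing dates excluded), fits the Weibull by
maximum likelihood and classifies the failure profile.
"""

from faersignal import synthetic
from faersignal.tto import compute_tto, tto_summary, weibull_mle

config = synthetic.SyntheticConfig(n_reports=30_000, seed=4)
cases, truth = synthetic.simulate(config)
exposed_ids = set(truth.records.loc[truth.records["exposed"], "primaryid"])

sample = compute_tto(cases, exposed_ids=exposed_ids, window=365)
print(f"retained onsets: n={sample.n} "
      f"(excluded: {sample.n_excluded_missing} missing dates, "
      f"{sample.n_excluded_negative} negative, {sample.n_excluded_window} beyond window)")

median, (q1, q3), n = tto_summary(sample)
print(f"median TTO {median:.1f} days (IQR {q1:.0f}-{q3:.0f})")

for label, window in (("one-year window", 365), ("uncapped", None)):
    fit = weibull_mle(compute_tto(cases, exposed_ids=exposed_ids, window=window))
    print(f"{label}: alpha = {fit.alpha:.1f} d, "
          f"beta = {fit.beta:.3f} (95% CI {fit.beta_ci95[0]:.3f}-{fit.beta_ci95[1]:.3f}) "
          f"-> {fit.failure_type}")
# shape < 1 with the whole CI below 1 -> "early" failures: the hazard of a
# new report decreases with time on the drug. The cohort's true shape is
# 0.9; the uncapped fit recovers it, while the windowed fit drifts toward
# 1 because dropping (rather than censoring) onsets beyond one year thins
# exactly the long-delay tail that makes the shape sub-exponential.
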