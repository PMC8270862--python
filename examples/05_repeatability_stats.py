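"""Test-retest repeatability metrics for an imaging biomarker.

Simulates two-visit whole-joint Ktrans data at the published variance
structure (sigma_b^2 = 2.1e-4, sigma_w^2 = 2.4e-5) and summarises it:
variance components, ICC with confidence interval, wSD, and the
smallest detectable difference.
"""

import numpy as np

from synodce.stats import repeatability_summary, standardized_mean_difference

rng = np.random.default_rng(0)
n = 14
level = 0.039 + rng.normal(0, np.sqrt(2.1e-4), n)
visit1 = level + rng.normal(0, np.sqrt(2.4e-5), n)
visit2 = level + rng.normal(0, np.sqrt(2.4e-5), n)

m = repeatability_summary((visit1, visit2), oa_values=visit1)
print(f"sigma_b^2 = {m.sigma_b2:.2e}   sigma_w^2 = {m.sigma_w2:.2e}")
print(f"ICC = {m.icc:.2f} (95% CI {m.icc_lo:.2f}, {m.icc_hi:.2f})")
print(f"scale = {m.scale}, wSD = {m.wsd_or_wcv:.4f} min^-1")
print(f"SDD = {m.sdd:.4f} min^-1 ({m.sdd_pct_of_mean:.0f}% of group mean)")

# Discrimination: at the study scale (14 vs 6) the SMD estimate is very
# noisy, so demonstrate the estimator at a stable n.
oa_big = 0.039 + rng.normal(0, np.sqrt(2.1e-4), 500)
hv_big = 0.025 + rng.normal(0, np.sqrt(2.1e-4), 500)
g = standardized_mean_difference(oa_big, hv_big)
print(f"group discrimination (n=500/500): SMD = {g.smd:.2f} "
      f"(means {g.mean_oa:.4f} vs {g.mean_hv:.4f})")
# The SDD (2.77 x wSD) is the smallest individual change distinguishable
# from measurement noise with 95% confidence; responsiveness is counted
# against it.
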