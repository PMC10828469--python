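"""Cohort statistics on slide scores: ANOVA, Tukey HSD, partial correlation.

Uses made-up slide scores so it runs instantly; swap in a scores.csv from
a real run to analyze actual output.
"""

import numpy as np

from egps import one_way_anova, partial_corr_given, pearson_corr, tukey_hsd, welch_t_test

rng = np.random.default_rng(3)
by_age = {age: rng.normal(loc=mu, scale=0.3, size=6)
          for age, mu in [("8", -1.0), ("16", -0.2), ("20", 0.4), ("32", 1.0)]}

anova = one_way_anova(by_age)
print(f"one-way ANOVA: F={anova.statistic:.2f}, p={anova.p_value:.3g}")
for r in tukey_hsd(by_age):
    print(f"  Tukey {r.pair[0]:>2} vs {r.pair[1]:>2}: diff={r.estimate:+.2f}, p_adj={r.p_value:.3g}")

# partial correlation: does a second score agree with eGPS beyond age?
ages = np.repeat([8.0, 16.0, 20.0, 32.0], 6)
egps = np.concatenate(list(by_age.values()))
grn_like = 0.05 * ages + rng.normal(scale=0.4, size=ages.size)
raw = pearson_corr(egps, grn_like)
partial = partial_corr_given(egps, grn_like, ages)
print(f"\nraw correlation r={raw.statistic:.2f} (p={raw.p_value:.3g})")
print(f"age-adjusted partial r={partial.statistic:.2f} (p={partial.p_value:.3g})")
# The raw r is inflated because both scores track age; the partial r asks
# what is left after regressing age out of both.

ctrl, treat = rng.normal(1.0, 0.3, 8), rng.normal(0.4, 0.3, 8)
w = welch_t_test(ctrl, treat)
print(f"\nintervention Welch t={w.statistic:.2f}, p={w.p_value:.3g} (treated lower by {w.estimate:.2f})")
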