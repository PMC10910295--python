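"""The rank-based statistical toolbox on a small worked dataset.

The Scheirer-Ray-Hare test is a rank-based two-way factorial analysis: rank
all values jointly, form factorial sums of squares on the ranks, and refer
H = SS_effect / (SS_total / (N-1)) to a chi-square distribution.  Effect
sizes use the Kruskal-Wallis eta-squared formula; significant interactions
are followed up with Dunn's pairwise z-tests on mean ranks.
"""

import numpy as np

from entolat import (
    FactorialSample,
    dunn_posthoc,
    kruskal_eta_squared,
    scheirer_ray_hare,
    two_proportion_z,
)

rng = np.random.default_rng(1)
# 20 units per cell; the light groups get a location shift (treatment effect)
values = np.concatenate([
    rng.gamma(4, 1.0, 20),   # dark / left
    rng.gamma(4, 1.0, 20),   # dark / right
    rng.gamma(4, 1.6, 20),   # light / left
    rng.gamma(4, 1.6, 20),   # light / right
])
treatment = np.repeat(["dark", "light"], 40)
hemisphere = np.tile(np.repeat(["left", "right"], 20), 2)

s = scheirer_ray_hare(FactorialSample(values, treatment, hemisphere))
print(f"treatment:   H(1) = {s.H_a:7.3f}, p = {s.p_a:.4f}, eta2 = {s.eta2_a:.3f}")
print(f"hemisphere:  H(1) = {s.H_b:7.3f}, p = {s.p_b:.4f}")
print(f"interaction: H(1) = {s.H_ab:7.3f}, p = {s.p_ab:.4f}")
eta2, label = kruskal_eta_squared(s.H_a, k=2, n=s.n)
print(f"treatment effect size: {eta2:.3f} ({label})")

groups = np.array([f"{t}_{h}" for t, h in zip(treatment, hemisphere)])
dunn = dunn_posthoc(values, groups, [("dark_left", "light_left"),
                                     ("dark_right", "light_right")])
for c in dunn.comparisons:
    print(f"Dunn {c.group_i} vs {c.group_j}: z = {c.z:6.3f}, "
          f"p = {c.p_raw:.4f} (Bonferroni {c.p_bonferroni:.4f})")

# Pooled two-proportion z-test comparing two bilateral-unit fractions
z, p, _ = two_proportion_z(478, 1544, 824, 1549)
print(f"\ntwo-proportion z = {z:.2f}, p = {p:.2e}")
# A large |z| means the two proportions (31% vs 53%) are incompatible with a
# common underlying rate.
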