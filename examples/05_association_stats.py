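"""The association statistics used around the expression analyses.

Pearson correlation between two markers across tumors, one-way ANOVA
across tissue groups, and a high/low-marker by alteration-status
contingency table tested with Fisher's exact and chi-square.
"""

import numpy as np

import coexnet as cx

rng = np.random.default_rng(0)

# Two markers measured across 100 tumors, essentially uncorrelated.
marker_a = rng.lognormal(4.0, 1.0, 100)
marker_b = rng.lognormal(3.0, 1.0, 100)
r = cx.pearson_r(np.log(marker_a), np.log(marker_b))
print(f"Pearson: r={r.statistic:.3f}, p={r.p_value:.3f} (n={r.n})")

# Expression across three tissue groups with a shifted third group.
groups = [rng.normal(4.0, 1.0, 40), rng.normal(4.1, 1.0, 40), rng.normal(5.0, 1.0, 40)]
a = cx.one_way_anova(groups)
print(f"ANOVA: F={a.statistic:.2f}, df={a.df}, p={a.p_value:.2e}")

# Marker-high/low vs alteration present/absent.
high = cx.dichotomize_high_low(np.log(marker_a))  # median split
altered = rng.random(100) < np.where(high, 0.5, 0.2)  # enriched in high
table = cx.ContingencyTable2x2(
    int((high & altered).sum()), int((high & ~altered).sum()),
    int((~high & altered).sum()), int((~high & ~altered).sum()),
    row_labels=("high", "low"), col_labels=("altered", "wild-type"),
)
f = cx.fisher_exact_2x2(table)
c = cx.chi_square_2x2(table)
print(f"Fisher: OR={f.estimate:.2f}, p={f.p_value:.4f}")
print(f"chi-square: X2={c.statistic:.2f}, p={c.p_value:.4f}")
# Both tests agree on direction; Fisher is exact at these counts.
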