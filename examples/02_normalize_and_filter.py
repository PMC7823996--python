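"""Quantile normalization and the above-blank filter.

Quantile normalization forces every sample onto the same intensity
distribution (compensating for cell growth); the filter keeps features whose
normalized signal beats the sterile-well blank at some time point in a
one-tailed equal-variance t-test (p < 0.05).
"""

import numpy as np

import metabodyn as md

design = md.StudyDesign(seed=0)
table, truth = md.generate_feature_table(
    design, n_features=500, frac_trend=0.5, noise_cv=0.1, seed=0
)
normalized = md.quantile_normalize(table)
col_means = normalized.values.mean(axis=0)
print(f"column means after normalization: all equal to "
      f"{col_means.iloc[0]:.6g} (spread {np.ptp(col_means.to_numpy()):.2e})")

result = md.above_blank_filter(normalized)
n_above = int(result.above_blank.sum())
print(f"features above blank: {n_above}/{table.n_features} "
      f"({100 * n_above / table.n_features:.1f}%)")
# Roughly half to three-quarters of features pass, comparable to the 31-58%
# range seen across real acquisition methods: quantile normalization erodes
# part of the raw cell/blank contrast by construction.
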