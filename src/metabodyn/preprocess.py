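"""Blank filtering and normalization.

Quantile normalization forces every sample's intensity distribution onto the
across-sample mean of order statistics, compensating for the growing cell size
(hence total metabolite content) of activating T cells. The blank filter
flags features whose quantile-normalized signal is greater than the
sterile-well blank for at least one time point by a one-tailed equal-variance
two-sample t-test at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FeatureTable

__all__ = ["quantile_normalize", "BlankFilterResult", "above_blank_filter"]


def quantile_normalize(table: FeatureTable) -> FeatureTable:
    """Quantile-normalize the intensity matrix across samples.

    Every column is mapped onto the identical reference vector (the
    across-column mean of the sorted values). Ties within a column receive the
    mean of the quantile values they span, matching the behaviour of the
    canonical reference implementation. Zeros (e.g. gap-filled absences)
    participate as ordinary values. Blanks, if present, are normalized
    together with the cell samples.
    """
    x = table.values.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("quantile normalization requires a complete matrix")
    n_feat, n_samp = x.shape
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(n_samp):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_feat)
        assigned[order] = ref
        # tied values receive the mean of the quantile values they span
        uniq, inv = np.unique(col, return_inverse=True)
        sums = np.bincount(inv, weights=assigned)
        counts = np.bincount(inv)
        out[:, j] = (sums / counts)[inv]
    values = pd.DataFrame(out, index=table.values.index, columns=table.values.columns)
    return table.with_values(values)


@dataclass
class BlankFilterResult:
    """Per-feature outcome of the above-blank t-test filter.

    ``p_values`` is a feature × time-point DataFrame of one-tailed p-values
    (cells > blank, equal variance); ``above_blank`` flags features whose
    minimum p over time points is below alpha.
    """

    p_values: pd.DataFrame
    above_blank: pd.Series
    alpha: float

    @property
    def min_p(self) -> pd.Series:
        return self.p_values.min(axis=1)

    def report(self) -> pd.DataFrame:
        """Tidy filter report: feature_id, min_p, above_blank."""
        return pd.DataFrame(
            {"min_p": self.min_p, "above_blank": self.above_blank}
        ).rename_axis("feature_id")


def above_blank_filter(table: FeatureTable, alpha: float = 0.05) -> BlankFilterResult:
    """Flag features detected above the sterile-well blank.

    For each feature and time point, a one-tailed equal-variance two-sample
    t-test compares the cell replicates against the blank replicates
    (alternative: cells greater). A feature is above blank if any time point
    gives p < alpha (no multiple-testing correction here, by design). The
    table should already be quantile normalized.
    """
    blanks = table.blank_ids
    if len(blanks) < 2:
        raise ValueError(
            "above_blank_filter needs >= 2 blank replicates; generate the study "
            "with the default blank_replicates=3"
        )
    time_points = table.time_points
    for t in time_points:
        if len(table.samples_at(t)) < 2:
            raise ValueError(f"time point {t} h has fewer than 2 replicates")
    blank_mat = table.values[blanks].to_numpy(dtype=float)
    pcols = {}
    for t in time_points:
        cells = table.values[table.samples_at(t)].to_numpy(dtype=float)
        res = stats.ttest_ind(
            cells, blank_mat, axis=1, equal_var=True, alternative="greater"
        )
        pcols[t] = res.pvalue
    p = pd.DataFrame(pcols, index=table.values.index)
    above = p.min(axis=1) < alpha
    return BlankFilterResult(p_values=p, above_blank=above, alpha=alpha)
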