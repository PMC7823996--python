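import numpy as np
import pandas as pd
import pytest

from metabodyn import FeatureTable, StudyDesign


@pytest.fixture(scope="session")
def design():
    return StudyDesign(seed=0)


def make_table(values: np.ndarray, mz=None, time_points=None, n_replicates=1,
               n_blanks=0) -> FeatureTable:
    """Small hand-built FeatureTable: values is features x samples; samples
    are laid out time-major then blanks."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    if time_points is None:
        n_cells = n_samp - n_blanks
        assert n_cells % n_replicates == 0
        time_points = list(range(0, 12 * (n_cells // n_replicates), 12))
    cols, rows = [], []
    for t in time_points:
        for r in range(n_replicates):
            cols.append(f"T{int(t):03d}_R{r + 1}")
            rows.append((float(t), r + 1, False))
    for b in range(n_blanks):
        cols.append(f"BLANK_B{b + 1}")
        rows.append((np.nan, b + 1, True))
    assert len(cols) == n_samp
    index = pd.Index([f"F{i + 1:03d}" for i in range(n_feat)], name="feature_id")
    sample_meta = pd.DataFrame(rows, columns=["time_h", "replicate", "is_blank"],
                               index=pd.Index(cols, name="sample_id"))
    return FeatureTable(
        pd.DataFrame(values, index=index, columns=cols),
        pd.DataFrame({"mz": mz if mz is not None else 100.0 + np.arange(n_feat)},
                     index=index),
        sample_meta,
    )
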