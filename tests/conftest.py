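import numpy as np
import pandas as pd
import pytest

from purinedelta import IntensityTable


def make_table(values, groups, scale="log10", **extra_meta):
    """Build an IntensityTable from a 2-D array and per-sample group labels."""
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    metabolites = [f"m{i:04d}" for i in range(1, m + 1)]
    sample_ids = [f"s{j:02d}" for j in range(1, n + 1)]
    meta = pd.DataFrame({"group": list(groups)}, index=sample_ids)
    for key, col in extra_meta.items():
        meta[key] = list(col)
    return IntensityTable(
        values=pd.DataFrame(values, index=metabolites, columns=sample_ids),
        samples=meta, scale=scale)


@pytest.fixture
def two_group_table():
    """6 samples (3 per group), 3 metabolites, no missing values."""
    rng = np.random.default_rng(7)
    return make_table(rng.normal(3.0, 0.2, size=(3, 6)), ["A"] * 3 + ["B"] * 3)
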