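import numpy as np
import pandas as pd
import pytest

from phylospatial import GeoTable, distance_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def make_table():
    """Factory for random geographic tables with an optional outcome/covariate."""

    def _make(n=20, seed=0, binary_outcome=False, covariate=True):
        r = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "id": [f"i{i:03d}" for i in range(n)],
                "lon": r.uniform(-180, 180, n),
                "lat": r.uniform(-60, 60, n),
            }
        )
        cov_cols = []
        if covariate:
            df["env"] = r.normal(size=n)
            cov_cols = ["env"]
        out_col = None
        if binary_outcome:
            eta = -0.2 + (0.5 * df["env"] if covariate else 0.0)
            df["outcome"] = r.binomial(1, 1.0 / (1.0 + np.exp(-eta)))
            if df["outcome"].nunique() < 2:  # force both classes at tiny n
                df.loc[df.index[0], "outcome"] = 1 - df["outcome"].iloc[0]
            out_col = "outcome"
        return GeoTable(df, outcome_col=out_col, covariate_cols=cov_cols)

    return _make


@pytest.fixture
def small_distance_matrix(make_table):
    return distance_matrix(make_table(n=12, seed=3))
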