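import numpy as np
import pandas as pd
import pytest

from ldscreen.expression import ExpressionMatrix
from ldscreen.screen_model import TitrationSeries
from ldscreen.simulate import STANDARD_GRID, simulate_titration


@pytest.fixture
def standard_grid():
    return STANDARD_GRID.copy()


@pytest.fixture
def clean_sigmoid():
    """Noiseless full-inhibition titration (EC50 9 nM, slope 1)."""
    return simulate_titration(
        {"top": 0.0, "bottom": -100.0, "ec50": 9e-9, "slope": 1.0}, noise_sd=0.0, seed=0
    )


@pytest.fixture
def flat_series(standard_grid):
    n = len(standard_grid)
    return TitrationSeries(
        compound_id="flat",
        concentrations=standard_grid,
        activity=np.zeros(n),
        cell_activity=np.zeros(n),
        mask=np.zeros(n, dtype=bool),
    )


def build_expression_matrix(values: np.ndarray, conditions, kinds=None, ids=None):
    """Assemble an ExpressionMatrix from a raw value array and per-sample
    condition labels (replicates numbered within condition)."""
    n_feat, n_samp = values.shape
    ids = ids if ids is not None else [f"g{i}" for i in range(n_feat)]
    kinds = kinds if kinds is not None else ["genic"] * n_feat
    reps, seen = [], {}
    cols = []
    for c in conditions:
        seen[c] = seen.get(c, 0) + 1
        reps.append(seen[c])
        cols.append(f"{c}_r{seen[c]}")
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=ids, columns=cols),
        feature_kind=pd.Series(kinds, index=ids),
        samples=pd.DataFrame(
            {"sample": cols, "condition": list(conditions), "replicate": reps}
        ),
    )
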