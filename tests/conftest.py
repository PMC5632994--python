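import numpy as np
import pandas as pd
import pytest

from twophase.strata import assign_strata, build_stratum_table


def make_four_strata(n_per_cell=10, p=2, seed=0, sigma=1.0):
    """Balanced four-cell sample with Gaussian main features."""
    rng = np.random.default_rng(seed)
    rows = []
    for xe in (0, 1):
        for y in (0, 1):
            for _ in range(n_per_cell):
                rows.append({"x_e": xe, "y": y})
    df = pd.DataFrame(rows)
    for j in range(p):
        df[f"x{j + 1}"] = rng.normal(scale=sigma, size=len(df))
    return assign_strata(df, "y", "x_e")


@pytest.fixture
def four_strata_sample():
    return make_four_strata(n_per_cell=10, p=2, seed=42)


@pytest.fixture
def weighted_table(four_strata_sample):
    """Weights (1, 5, 2, 9) via selection probabilities (0.9, 0.18, 0.45, 0.1)."""
    p_select = {(0, 0): 0.9, (0, 1): 0.18, (1, 0): 0.45, (1, 1): 0.1}
    return build_stratum_table(four_strata_sample, p_select=p_select)


@pytest.fixture
def unit_table(four_strata_sample):
    """All selection probabilities equal -> all weights 1."""
    p_select = {c: 0.25 for c in four_strata_sample.strata}
    return build_stratum_table(four_strata_sample, p_select=p_select)
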