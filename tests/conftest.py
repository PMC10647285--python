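import numpy as np
import pandas as pd
import pytest

from metstab.data_model import CellMeans, MetTrial


def trial_from_cells(matrix, r: int = 1, genotypes=None, environments=None,
                     rep_noise: np.ndarray | None = None) -> MetTrial:
    """Build a balanced trial whose cell means equal ``matrix`` exactly.

    With r > 1 every replicate repeats the cell value (zero within-cell
    variance) unless ``rep_noise`` (g, e, r, summing to 0 over reps) is given.
    """
    matrix = np.asarray(matrix, dtype=float)
    g, e = matrix.shape
    genotypes = genotypes or [f"G{i+1:02d}" for i in range(g)]
    environments = environments or [f"E{j+1:02d}" for j in range(e)]
    rows = []
    for i, gen in enumerate(genotypes):
        for j, env in enumerate(environments):
            for k in range(r):
                val = matrix[i, j]
                if rep_noise is not None:
                    val = val + rep_noise[i, j, k]
                rows.append((env, gen, f"R{k+1}", val))
    return MetTrial(pd.DataFrame(rows, columns=["env", "gen", "rep", "yield"]))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_trial(rng):
    """Random balanced 4 x 3 x 2 trial (all values positive)."""
    y = 50.0 + 10.0 * rng.standard_normal((4, 3, 2))
    noise = y - y.mean(axis=2, keepdims=True)
    return trial_from_cells(y.mean(axis=2), r=2, rep_noise=noise)


@pytest.fixture
def cm_random(rng):
    """Random 6 x 5 cell-means matrix."""
    return CellMeans.from_matrix(100.0 + 20.0 * rng.standard_normal((6, 5)))
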