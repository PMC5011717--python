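import numpy as np
import pandas as pd
import pytest

from wbdecon import ExpressionDataset, make_annotations


@pytest.fixture
def small_dataset():
    """6-gene, 6-sample annotated linear-scale dataset (3 case / 3 control)."""
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(6)]
    samples = [f"s{i}" for i in range(6)]
    values = pd.DataFrame(
        rng.lognormal(3, 0.5, size=(6, 6)), index=genes, columns=samples
    )
    ann = make_annotations(
        samples, "ds1", ["case"] * 3 + ["control"] * 3,
        ["flu"] * 3 + [None] * 3,
    )
    return ExpressionDataset(values, "linear", ann)


def grid_nnls_2d(A, y, upper=1.5, step=1e-3):
    """Brute-force NNLS oracle for two unknowns.

    Evaluates ||y - A g||^2 on a regular grid over [0, upper]^2 and
    returns the arg-min.  Independent of scipy's active-set solver.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    g = np.arange(0.0, upper + step / 2, step)
    Q = A.T @ A
    b = A.T @ y
    # ||y||^2 constant; minimize g'Qg - 2 b'g over the grid
    g1 = g[:, None]
    g2 = g[None, :]
    obj = (
        Q[0, 0] * g1**2
        + 2 * Q[0, 1] * g1 * g2
        + Q[1, 1] * g2**2
        - 2 * (b[0] * g1 + b[1] * g2)
    )
    i, j = np.unravel_index(np.argmin(obj), obj.shape)
    return np.array([g[i], g[j]])
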