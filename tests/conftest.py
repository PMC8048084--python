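import numpy as np
import pandas as pd
import pytest

from gxrx import ExpressionMatrix


@pytest.fixture
def brute_force_knn():
    """Independent kNN oracle: full distance sort with explicit tie rule.

    Computes plain squared Euclidean distances pairwise and sorts
    (distance, column index) lexicographically, so it shares no code path
    with the package's partition-based selection.
    """

    def predict(pool, values, query, k, exclude=None):
        pool = np.asarray(pool, dtype=float)
        if pool.ndim == 1:
            pool = pool[None, :]
        query = np.atleast_1d(np.asarray(query, dtype=float))
        dists = []
        for j in range(pool.shape[1]):
            if j == exclude:
                continue
            dists.append((float(((pool[:, j] - query) ** 2).sum()), j))
        dists.sort()
        chosen = [j for _, j in dists[:k]]
        return float(np.mean([values[j] for j in chosen]))

    return predict


@pytest.fixture
def brute_force_loo(brute_force_knn):
    def predict(X, y, k):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return np.array(
            [brute_force_knn(X, y, X[:, i], k, exclude=i) for i in range(X.shape[1])]
        )

    return predict


def make_expression(values, genes=None, samples=None, state="raw", meta=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        transform_state=state,
        meta=meta,
    )


@pytest.fixture
def expr_factory():
    return make_expression
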