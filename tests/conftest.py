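import numpy as np
import pandas as pd
import pytest

from respanel import ExpressionMatrix
from respanel.datamodel_io import NONRESPONDER, RESPONDER


def matrix_from_rows(rows: dict[str, list[float]], samples: list[str] | None = None):
    n = len(next(iter(rows.values())))
    samples = samples or [f"s{i + 1}" for i in range(n)]
    return ExpressionMatrix(pd.DataFrame(rows, index=samples).T)


def two_group_labels(n_resp: int, n_non: int) -> list[str]:
    return [RESPONDER] * n_resp + [NONRESPONDER] * n_non


@pytest.fixture
def separable_matrix():
    """Two genes, cleanly separated groups (3 responders vs 3 non-responders)."""
    return matrix_from_rows({
        "gA": [10.0, 10.2, 9.8, 1.0, 1.2, 0.8],
        "gB": [5.0, 5.5, 4.5, 5.1, 5.4, 4.6],
    })


@pytest.fixture
def separable_labels():
    return two_group_labels(3, 3)


@pytest.fixture
def xor_like_matrix():
    """Genes jointly separable along g2 - g1, but weakly informative alone.

    Responders lie on the line y = x, non-responders on y = x + 1: the
    difference direction separates perfectly while each coordinate's
    group distributions overlap (g1's are identical).
    """
    return matrix_from_rows({
        "g1": [0.0, 1.0, 2.0, 0.0, 1.0, 2.0],
        "g2": [0.0, 1.0, 2.0, 1.0, 2.0, 3.0],
    })


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
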