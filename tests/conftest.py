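import numpy as np
import pytest

from bis.data_io import ExpressionMatrix


def make_matrix(values, row_prefix="c", col_prefix="g", layer_tag="raw_counts"):
    values = np.asarray(values, dtype=float)
    rows = [f"{row_prefix}{i+1}" for i in range(values.shape[0])]
    cols = [f"{col_prefix}{j+1}" for j in range(values.shape[1])]
    return ExpressionMatrix(values, rows, cols, layer_tag)


@pytest.fixture
def small_counts():
    rng = np.random.default_rng(7)
    return make_matrix(rng.poisson(5.0, size=(30, 12)))
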