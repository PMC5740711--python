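import numpy as np
import pytest

from superdelta import ExpressionMatrix, GroupDesign


def make_matrix(values, gene_prefix="g", sample_prefix="s") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"{gene_prefix}{i+1}" for i in range(values.shape[0])],
        [f"{sample_prefix}{j+1}" for j in range(values.shape[1])],
    )


def make_design(n_a: int, n_b: int, sample_prefix="s") -> GroupDesign:
    ids = [f"{sample_prefix}{j+1}" for j in range(n_a + n_b)]
    return GroupDesign(
        {s: ("A" if j < n_a else "B") for j, s in enumerate(ids)}, sample_ids=ids
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def design_22():
    return make_design(2, 2)


@pytest.fixture
def design_55():
    return make_design(5, 5)
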