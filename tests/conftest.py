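import numpy as np
import pytest

from gdcoxs.io import ConditionLabels, MatrixKind, OmicsMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_matrix(values, kind=MatrixKind.GE, gene_prefix="g", sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    return OmicsMatrix(
        values,
        [f"{gene_prefix}{i}" for i in range(values.shape[0])],
        [f"{sample_prefix}{j}" for j in range(values.shape[1])],
        kind,
    )


@pytest.fixture
def paired_matrices(rng):
    """Aligned ternary CNA and continuous GE matrices, 12 genes x 24 samples."""
    cna_vals = rng.choice([-1.0, 0.0, 1.0], size=(12, 24), p=[0.15, 0.7, 0.15])
    ge_vals = cna_vals + rng.standard_normal((12, 24))
    cna = make_matrix(cna_vals, MatrixKind.CNA)
    ge = make_matrix(ge_vals, MatrixKind.GE)
    return cna, ge


@pytest.fixture
def two_group_labels():
    """12 + 12 sample labels over s0..s23."""
    return ConditionLabels(
        {f"s{j}": ("A" if j < 12 else "B") for j in range(24)}
    )
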