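import numpy as np
import pandas as pd
import pytest

from matreotype import ExpressionMatrix, generate_bulk_cohort, tmm_normalize_log2
from matreotype.preprocess import ZScaledMatrix
from matreotype.synthetic import SyntheticConfig


def make_zscaled(values: np.ndarray, genes=None, samples=None) -> ZScaledMatrix:
    """Wrap a raw genes x samples array as a ZScaledMatrix without rescaling.

    Convenience for tests that construct z-values directly.
    """
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    return ZScaledMatrix(df, df.mean(axis=1), df.std(axis=1, ddof=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort shared by read-only pipeline tests."""
    config = SyntheticConfig(
        n_tumor=60, n_non_tumor=20, n_genes_total=400, n_matrisome=150,
        n_signature=10, block_spec=((20, 0.7), (15, 0.5)), seed=11,
    )
    return generate_bulk_cohort(config)


@pytest.fixture(scope="session")
def small_log2(small_cohort):
    return tmm_normalize_log2(small_cohort["expression"])


@pytest.fixture()
def toy_counts() -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    counts = rng.negative_binomial(5, 0.05, size=(50, 4)).astype(float)
    counts[0, 0] *= 40
    df = pd.DataFrame(counts, index=[f"g{i}" for i in range(50)],
                      columns=list("ABCD"))
    return ExpressionMatrix(df, "counts")
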