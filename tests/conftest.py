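import numpy as np
import pandas as pd
import pytest

from bcap import CqMatrix, NormalizedMatrix


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_cq() -> CqMatrix:
    """4 miRNAs x 4 samples with one missing cell."""
    vals = pd.DataFrame(
        [
            [20.0, 21.0, 22.0, 23.0],
            [25.0, 24.0, 26.0, np.nan],
            [30.0, 31.0, 29.0, 30.0],
            [22.0, 22.5, 23.0, 21.5],
        ],
        index=["miR-a", "miR-b", "miR-c", "miR-d"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return CqMatrix(vals)


def random_norm_matrix(rng, n_mirnas=8, n_samples=30, prefix="m") -> NormalizedMatrix:
    vals = pd.DataFrame(
        rng.normal(0.0, 1.0, (n_mirnas, n_samples)),
        index=[f"{prefix}{i:02d}" for i in range(n_mirnas)],
        columns=[f"s{j:03d}" for j in range(n_samples)],
    )
    return NormalizedMatrix(vals)
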