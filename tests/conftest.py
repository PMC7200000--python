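"""Shared fixtures: small genotype matrices and capture datasets built in memory."""

import numpy as np
import pandas as pd
import pytest

from gartergen import CaptureDataset, GenotypeMatrix


@pytest.fixture
def hw_locus():
    """One locus at exact Hardy-Weinberg proportions, p = 0.5."""
    return GenotypeMatrix(
        sample_ids=["a", "b", "c", "d"],
        locus_ids=["L1"],
        dosages=np.array([[0], [1], [1], [2]]),
        population=["p1"] * 4,
    )


@pytest.fixture
def two_pop_matrix():
    """Two populations of 6 with mixed polymorphism and some missing calls."""
    rng = np.random.default_rng(42)
    d = rng.integers(0, 3, size=(12, 20)).astype(np.int16)
    d[0, 0] = -1
    d[5, 3] = -1
    return GenotypeMatrix(
        sample_ids=[f"i{k}" for k in range(12)],
        locus_ids=[f"L{j}" for j in range(20)],
        dosages=d,
        population=["A"] * 6 + ["B"] * 6,
    )


@pytest.fixture
def small_capture_dataset():
    """Three observed histories over two occasions at one site."""
    return CaptureDataset(
        site="s",
        occasions=["2018-01-01", "2018-01-02"],
        air_temp=np.array([15.0, 16.0]),
        individuals=pd.DataFrame(
            {
                "individual_id": ["a", "b", "c"],
                "sex": ["F", "M", "U"],
                "svl_mm": [400.0, 420.0, 390.0],
            }
        ),
        captures=np.array([[1, 0], [1, 1], [0, 1]], dtype=np.int8),
    )
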