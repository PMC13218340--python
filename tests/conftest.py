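import numpy as np
import pandas as pd
import pytest

from groupfdr.io_model import AnnotationRecord, ExpressionTable
from groupfdr.synthetic import SimulationParams, generate_dataset


@pytest.fixture
def toy_annotation() -> list[AnnotationRecord]:
    """Six miRNAs: chr1+p x3, chr1-p x1 (a strand-level singleton), chr2+q x2."""
    return [
        AnnotationRecord("mirA", "1", "+", "p", 100),
        AnnotationRecord("mirB", "1", "+", "p", 500),
        AnnotationRecord("mirC", "1", "+", "p", 900),
        AnnotationRecord("mirD", "1", "-", "p", 650),
        AnnotationRecord("mirE", "2", "+", "q", 200),
        AnnotationRecord("mirF", "2", "+", "q", 700),
    ]


@pytest.fixture
def toy_expression() -> ExpressionTable:
    patients = ["P01", "P02", "P03"]
    mirnas = ["mirA", "mirB"]
    tumor = pd.DataFrame([[5.0, 6.0, 7.0], [1.0, np.nan, 2.0]], index=mirnas, columns=patients)
    normal = pd.DataFrame([[3.0, 3.5, 4.0], [2.0, np.nan, 3.0]], index=mirnas, columns=patients)
    return ExpressionTable(tumor=tumor, normal=normal)


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic miRNAome shared across tests (seed 0)."""
    return generate_dataset(SimulationParams(seed=0))


@pytest.fixture(scope="session")
def small_dataset():
    """A faster, smaller synthetic dataset for pipeline-level tests."""
    params = SimulationParams(seed=11, n_mirnas=120, n_chromosomes=8)
    return generate_dataset(params), params
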