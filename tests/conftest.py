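import numpy as np
import pandas as pd
import pytest

from scalesel.data_model import CandidateDesign, ColumnInfo


def make_design(
    X: np.ndarray,
    names: list[str] | None = None,
    concepts: list[str] | None = None,
    scales: list[str] | None = None,
) -> CandidateDesign:
    """Wrap a numeric matrix as a CandidateDesign; by default every column is
    its own concept at the CT scale (i.e. an unconstrained design)."""
    p = X.shape[1]
    names = names or [f"x{i}" for i in range(p)]
    concepts = concepts or names
    scales = scales or ["CT"] * p
    cols = [
        ColumnInfo(concepts[i], scales[i], names[i], i + 1) for i in range(p)
    ]
    return CandidateDesign(pd.DataFrame(X, columns=names), cols)


def standardized_random_design(
    rng: np.random.Generator, n: int, p: int
) -> CandidateDesign:
    X = rng.standard_normal((n, p))
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    return make_design(X)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_308)
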