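import numpy as np
import pandas as pd
import pytest

from oncomito import OmicsMatrix, oncocytoma_v1, synthetic_genome


@pytest.fixture(scope="session")
def config():
    return oncocytoma_v1()


@pytest.fixture(scope="session")
def genome():
    return synthetic_genome()


def make_matrix(values: dict[str, list[float]], features: list[str]) -> OmicsMatrix:
    """Build a small paired matrix; sample names follow P<i>_T / P<i>_N."""
    frame = pd.DataFrame(values, index=features, dtype=float)
    groups = {s: ("tumor" if s.endswith("_T") else "normal") for s in frame.columns}
    pairs = {s: s[:-2] for s in frame.columns}
    return OmicsMatrix(frame, groups, pairs)


@pytest.fixture
def paired_matrix_3x4():
    return make_matrix(
        {
            "P1_T": [10.0, 12.0, 8.0],
            "P2_T": [11.0, np.nan, 9.0],
            "P1_N": [10.5, 11.0, 8.2],
            "P2_N": [10.8, 11.5, 8.1],
        },
        ["F1", "F2", "F3"],
    )
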