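from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from fluidprofiler.io_formats import AccessionSet, IntensityMatrix

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture
def tiny_matrix() -> IntensityMatrix:
    """4 proteins x 3 patients, hand-sized for by-hand checks."""
    values = pd.DataFrame(
        {
            "S1": [10.0, 5.0, np.nan, 25.0],
            "S2": [20.0, 10.0, 30.0, 20.0],
            "S3": [15.0, np.nan, 40.0, 25.0],
        },
        index=["IPI00000001", "IPI00000002", "IPI00000003", "IPI00000004"],
    )
    scores = pd.Series([5.0, 3.0, 9.0, 7.0], index=values.index)
    return IntensityMatrix(values=values, scores=scores)


def make_sets(a, b, c) -> tuple[AccessionSet, AccessionSet, AccessionSet]:
    return (
        AccessionSet.from_iterable("A", a),
        AccessionSet.from_iterable("B", b),
        AccessionSet.from_iterable("C", c),
    )
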