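import numpy as np
import pandas as pd
import pytest

from stemwall import generate_network_matrix, generate_stem_matrix
from stemwall.containers import ExpressionMatrix, StudyDesign


@pytest.fixture(scope="session")
def design():
    return StudyDesign()


@pytest.fixture(scope="session")
def stem_500(design):
    """Small stem matrix with default planted fractions."""
    return generate_stem_matrix(500, design, seed=101)


@pytest.fixture(scope="session")
def stem_2000(design):
    return generate_stem_matrix(2000, design, seed=202)


@pytest.fixture(scope="session")
def network_2000(design, stem_2000):
    stem, truth = stem_2000
    return generate_network_matrix(stem, truth, design, seed=303)


def matrix_from_array(values: np.ndarray, probe_ids=None, design: StudyDesign | None = None,
                      stem_only: bool = True) -> ExpressionMatrix:
    """Wrap a raw array as an ExpressionMatrix over the stem design (or the
    full 37-chip design when the array is that wide)."""
    design = design or StudyDesign()
    table = design.stem_design() if stem_only else design.network_design()
    n_rows, n_cols = values.shape
    cols = list(table.index)[:n_cols]
    if probe_ids is None:
        probe_ids = [f"P{i:04d}" for i in range(n_rows)]
    frame = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=cols)
    return ExpressionMatrix(frame, table, n_chip=61281)
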