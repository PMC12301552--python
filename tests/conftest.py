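import numpy as np
import pandas as pd
import pytest

from refintervals import MethodPolicy, StudyTable


@pytest.fixture
def policy() -> MethodPolicy:
    return MethodPolicy()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def make_table(rows: list[dict]) -> StudyTable:
    df = pd.DataFrame(rows, columns=["animal_id", "sex", "measurand", "unit", "value"])
    return StudyTable(df=df, partition_columns=("sex",))


@pytest.fixture
def hb_table() -> StudyTable:
    """60 male + 30 female hemoglobin-like values."""
    rng = np.random.default_rng(1)
    rows = []
    for i in range(60):
        rows.append(
            {"animal_id": f"M{i}", "sex": "M", "measurand": "Hb", "unit": "g/dl",
             "value": float(rng.normal(11.5, 1.4))}
        )
    for i in range(30):
        rows.append(
            {"animal_id": f"F{i}", "sex": "F", "measurand": "Hb", "unit": "g/dl",
             "value": float(rng.normal(12.5, 2.2))}
        )
    return make_table(rows)
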