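import numpy as np
import pandas as pd
import pytest

from neurodiff.datamodel import (
    Diagnosis,
    FeatureSetSpec,
    FeatureTable,
    FieldStrength,
    Sex,
    SubjectRecord,
    default_column_names,
)


#: six-block layout small enough for unit tests (total 28 features)
TINY_SPECS = (
    FeatureSetSpec("volume", 500, 8),
    FeatureSetSpec("volume", 1000, 6),
    FeatureSetSpec("volume", 2000, 4),
    FeatureSetSpec("thickness", 500, 5),
    FeatureSetSpec("thickness", 1000, 3),
    FeatureSetSpec("thickness", 2000, 2),
)


@pytest.fixture
def tiny_specs():
    return TINY_SPECS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(
    sid="S1",
    visit="v0",
    diagnosis=Diagnosis.NC,
    age=70.0,
    sex=Sex.M,
    icv=1.5e6,
    fs=FieldStrength.T3,
    site="site0",
    scanner="scanner0",
):
    return SubjectRecord(sid, visit, diagnosis, age, sex, icv, fs, site, scanner)


@pytest.fixture
def make_subject_record():
    return make_record


def random_table(specs, n_rows, seed=0, kind="raw"):
    rng = np.random.default_rng(seed)
    total = sum(s.dimension for s in specs)
    values = rng.normal(size=(n_rows, total)) * 10 + 100
    ids = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n_rows)],
            "visit_id": ["v0"] * n_rows,
        }
    )
    return FeatureTable(ids, values, default_column_names(specs), specs, kind)


@pytest.fixture
def make_table():
    return random_table
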