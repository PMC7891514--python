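import numpy as np
import pandas as pd
import pytest

from intraref import (
    LongitudinalPanel,
    default_analyte_configs,
    study_like_bundle,
)


def make_panel(values_by_subject, analyte="SYN", units="", sexes=None):
    """Build a panel from {subject_id: sequence-of-values}."""
    rows = []
    for sid, vals in values_by_subject.items():
        sex = (sexes or {}).get(sid, "unspecified")
        for j, v in enumerate(vals, start=1):
            rows.append({"subject_id": sid, "sex": sex, "visit_index": j, "value": float(v)})
    return LongitudinalPanel(analyte=analyte, units=units, data=pd.DataFrame(rows))


@pytest.fixture(scope="session")
def configs():
    return default_analyte_configs()


@pytest.fixture(scope="session")
def study_bundle():
    return study_like_bundle(20260930)


@pytest.fixture(scope="session")
def trf_panel(study_bundle):
    return study_bundle["TRF"]


@pytest.fixture
def tiny_panel():
    """3 subjects x 4 visits, hand-sized values."""
    rng = np.random.default_rng(7)
    return make_panel({f"P{i}": 50 + 10 * i + rng.normal(0, 2, 4) for i in range(3)})
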