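import io

import numpy as np
import pytest

from equity_audit.data_model import DEFAULT_TREATMENTS, read_cohort

_HEADER = (
    ["patient_id", "age", "gender", "ethnicity", "honos6_initial", "honos6_followup"]
    + [f"uptake_{t}" for t in DEFAULT_TREATMENTS]
)


def cohort_csv(rows: list[dict]) -> io.StringIO:
    """Build a canonical cohort CSV stream from partial row dicts."""
    lines = [",".join(_HEADER)]
    for i, overrides in enumerate(rows):
        base = {
            "patient_id": f"P{i:03d}",
            "age": "30",
            "gender": "Female",
            "ethnicity": "White",
            "honos6_initial": "3",
            "honos6_followup": "2",
        }
        base.update({f"uptake_{t}": "not_offered" for t in DEFAULT_TREATMENTS})
        base.update(overrides)
        lines.append(",".join(base[c] for c in _HEADER))
    return io.StringIO("\n".join(lines) + "\n")


@pytest.fixture
def make_cohort():
    """Factory turning partial row dicts into a parsed CohortTable."""

    def _make(rows: list[dict]):
        return read_cohort(cohort_csv(rows))

    return _make


@pytest.fixture
def toy_five_records():
    """Five records: one under-age, one missing follow-up, three analysable."""
    return [
        {"patient_id": "A", "age": "25"},
        {"patient_id": "B", "age": "17"},
        {"patient_id": "C", "age": "40", "honos6_followup": ""},
        {"patient_id": "D", "age": "55", "gender": "Male"},
        {"patient_id": "E", "age": "19", "ethnicity": "Black or Black British"},
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
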