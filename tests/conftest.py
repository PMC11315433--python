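import math

import pandas as pd
import pytest

from canalarea.cohort import Cohort
from canalarea.simulate import default_params, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One calibrated synthetic cohort (803 records/level), fixed seed."""
    return generate_cohort(default_params(seed=7))


@pytest.fixture()
def toy_cohort():
    """Three hand-made records at C2-3 plus two at C6-7."""
    rows = [
        ("P1", "C2-3", 12.0, 25.0, 250.0),
        ("P2", "C2-3", 13.5, 24.0, 270.0),
        ("P3", "C2-3", 11.0, 26.0, 240.0),
        ("P1", "C6-7", 12.5, 26.0, 260.0),
        ("P2", "C6-7", 13.0, 27.0, 280.0),
    ]
    return Cohort.from_records(rows, provenance="toy")


def make_cohort_from_arrays(level, ap, ipd, measured, prefix="P"):
    """Build a single-level cohort from parallel measurement arrays."""
    df = pd.DataFrame(
        {
            "patient_id": [f"{prefix}{i}" for i in range(len(ap))],
            "level": level,
            "ap_diameter_mm": ap,
            "ipd_mm": ipd,
            "measured_area_mm2": measured,
        }
    )
    return Cohort(df, provenance="arrays")


def ellipse_exact_cohort(level="C2-3", n=5):
    """Cohort whose measured area equals the ellipse approximation exactly."""
    ap = [10.0 + i for i in range(n)]
    ipd = [20.0 + 2 * i for i in range(n)]
    measured = [math.pi * (b / 2) * (a / 2) for a, b in zip(ap, ipd)]
    return make_cohort_from_arrays(level, ap, ipd, measured)
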