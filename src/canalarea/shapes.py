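"""Closed-form shape approximations of canal cross-sectional area.

Each approximation treats the canal cross-section as a simple shape whose
two defining extents are the anteroposterior diameter (AP) and the
interpedicular distance (IPD), both in mm:

========== =============================
ellipse    pi * (IPD/2) * (AP/2)
triangle   (1/2) * IPD * AP
rectangle  IPD * AP
========== =============================

All three are positive multiples of the product AP x IPD, so exactly
``ellipse = (pi/4) * rectangle`` and ``triangle = rectangle / 2`` hold per
record, and all three share one Pearson correlation with any reference
measurement at a level.  Computations are double precision with no internal
rounding; display rounding belongs to the report layer.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = [
    "ellipse_area",
    "triangle_area",
    "rectangle_area",
    "approximate_cohort",
    "APPROXIMATIONS",
]

#: Names of the three pure shape approximations, in reporting order.
APPROXIMATIONS: tuple[str, ...] = ("ellipse", "triangle", "rectangle")


def _check_positive(ap, ipd) -> tuple[np.ndarray, np.ndarray]:
    ap = np.asarray(ap, dtype=float)
    ipd = np.asarray(ipd, dtype=float)
    if np.any(ap <= 0.0) or np.any(ipd <= 0.0):
        raise ValueError("ap and ipd must be strictly positive lengths (mm)")
    return ap, ipd


def ellipse_area(ap, ipd):
    """Elliptical area pi*(ipd/2)*(ap/2) in mm^2. Accepts scalars or arrays."""
    ap, ipd = _check_positive(ap, ipd)
    return math.pi * (ipd / 2.0) * (ap / 2.0)


def triangle_area(ap, ipd):
    """Triangular area (1/2)*ipd*ap in mm^2. Accepts scalars or arrays."""
    ap, ipd = _check_positive(ap, ipd)
    return 0.5 * ipd * ap


def rectangle_area(ap, ipd):
    """Rectangular area ipd*ap in mm^2. Accepts scalars or arrays."""
    ap, ipd = _check_positive(ap, ipd)
    return ipd * ap


def approximate_cohort(cohort: Cohort) -> pd.DataFrame:
    """Compute all three shape approximations for every record.

    Returns a DataFrame aligned to ``cohort.df`` (same index, same order)
    with columns ``ellipse``, ``triangle``, ``rectangle`` in mm^2.
    """
    ap = cohort.df["ap_diameter_mm"].to_numpy()
    ipd = cohort.df["ipd_mm"].to_numpy()
    if len(ap) == 0:
        return pd.DataFrame(columns=list(APPROXIMATIONS), dtype=float)
    return pd.DataFrame(
        {
            "ellipse": ellipse_area(ap, ipd),
            "triangle": triangle_area(ap, ipd),
            "rectangle": rectangle_area(ap, ipd),
        },
        index=cohort.df.index,
    )
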