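"""Second-order approximation (SOA) of canal area.

The ellipse approximation consistently underestimates the cervical canal
area while the rectangle consistently overestimates it.  The SOA bridges
the gap by keeping the full ellipse value and adding a small per-level
fraction of the rectangle value::

    soa = ellipse + c(level) * rectangle

Because both terms are multiples of AP x IPD, the SOA collapses
algebraically to ``(pi/4 + c) * AP * IPD`` — a single per-level scalar
times the product of the two linear measurements.

Two estimators of the rectangle weight ``c`` (ellipse weight fixed at 1)
are provided:

``least_squares``
    ``argmin_c sum((measured - ellipse - c*rectangle)^2)``, closed form
    ``c = sum(rect * (measured - ellipse)) / sum(rect^2)``.
``mean_match``
    ``c = mean(measured - ellipse) / mean(rectangle)``, which forces the
    paired mean difference between SOA and measurement to zero exactly, so
    the paired t-statistic is exactly 0 (p = 1).

The built-in coefficients are the published per-level values fitted on the
803-patient reference cohort.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd
import yaml

from .cohort import LEVELS, Cohort, canonical_level
from .exceptions import ConfigurationError, FittingError
from .shapes import approximate_cohort

__all__ = [
    "SOACoefficients",
    "builtin_coefficients",
    "apply_soa",
    "soa_mean_from_level_means",
    "SOAFit",
    "fit_soa_coefficient",
    "fitted_soa_pipeline",
]

FitMethod = Literal["least_squares", "mean_match"]

#: Published per-level rectangle weights (ellipse weight fixed at 1),
#: fitted on the reference cohort.
_BUILTIN: dict[str, float] = {
    "C2-3": 0.07091,
    "C3-4": 0.046525,
    "C4-5": 0.041866,
    "C5-6": 0.0329399,
    "C6-7": 0.0210019,
}


class SOACoefficients(dict):
    """Per-level rectangle weights, a ``{level: c}`` mapping.

    The ellipse weight is fixed at 1 and not stored.  Serializable to and
    from small YAML/JSON files keyed by level.
    """

    def __init__(self, weights: dict[str, float]):
        super().__init__(
            {canonical_level(k): float(v) for k, v in weights.items()}
        )
        for lvl, c in self.items():
            if not math.isfinite(c):
                raise ConfigurationError(f"non-finite coefficient at {lvl}: {c}")

    def for_level(self, level: str) -> float:
        level = canonical_level(level)
        if level not in self:
            raise ConfigurationError(f"no SOA coefficient for level {level}")
        return self[level]

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        ordered = {lvl: self[lvl] for lvl in LEVELS if lvl in self}
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(ordered, indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(ordered, sort_keys=False))
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "SOACoefficients":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        return cls(data)


def builtin_coefficients() -> SOACoefficients:
    """The published per-level coefficients, verbatim."""
    return SOACoefficients(_BUILTIN)


def apply_soa(
    approximations: pd.DataFrame,
    levels: pd.Series,
    coefficients: SOACoefficients,
) -> pd.Series:
    """Per-record SOA area ``ellipse + c(level) * rectangle``, mm^2.

    ``approximations`` and ``levels`` must be index-aligned (both come from
    the same cohort).  By linearity the level mean of the result equals
    ``mean(ellipse) + c * mean(rectangle)``.
    """
    if not approximations.index.equals(levels.index):
        raise ValueError("approximations and levels must be index-aligned")
    c = levels.map(lambda lvl: coefficients.for_level(lvl)).astype(float)
    out = approximations["ellipse"] + c * approximations["rectangle"]
    out.name = "soa"
    return out


def soa_mean_from_level_means(
    ellipse_mean: float, rectangle_mean: float, c: float
) -> float:
    """Level-mean SOA from level-mean inputs (exact by linearity), mm^2."""
    return ellipse_mean + c * rectangle_mean


class SOAFit(NamedTuple):
    """A fitted rectangle weight with its standard error and fit size."""

    coefficient: float
    stderr: float
    n: int
    method: str


def fit_soa_coefficient(
    cohort: Cohort,
    approximations: pd.DataFrame,
    level: str,
    method: FitMethod = "least_squares",
) -> SOAFit:
    """Fit the rectangle weight ``c`` at one level.

    See the module docstring for the two estimators.  Standard errors come
    from the residual variance: for least squares
    ``se = sd(resid) / sqrt(sum(rect^2))`` (regression through the origin on
    the ellipse residual); for mean_match the delta-method analogue
    ``se = sd(resid) / (mean(rect) * sqrt(n))``.
    """
    level = canonical_level(level)
    mask = cohort.level_mask(level)
    n = int(mask.sum())
    if n < 2:
        raise FittingError(f"level {level}: need >= 2 records to fit, got {n}")
    measured = cohort.df.loc[mask, "measured_area_mm2"].to_numpy()
    ellipse = approximations.loc[mask, "ellipse"].to_numpy()
    rect = approximations.loc[mask, "rectangle"].to_numpy()
    target = measured - ellipse

    if method == "least_squares":
        if rect.std(ddof=1) == 0.0:
            raise FittingError(
                f"level {level}: rectangle areas are all identical; "
                "least_squares fit is degenerate"
            )
        c = float(np.sum(rect * target) / np.sum(rect * rect))
        resid = target - c * rect
        sigma = resid.std(ddof=1)
        se = float(sigma / math.sqrt(np.sum(rect * rect)))
    elif method == "mean_match":
        c = float(target.mean() / rect.mean())
        resid = target - c * rect
        sigma = resid.std(ddof=1)
        se = float(sigma / (rect.mean() * math.sqrt(n)))
    else:
        raise ValueError(f"unknown fit method {method!r}")
    return SOAFit(coefficient=c, stderr=se, n=n, method=method)


def fitted_soa_pipeline(
    cohort: Cohort,
    method: FitMethod = "least_squares",
    approximations: pd.DataFrame | None = None,
) -> tuple[SOACoefficients, pd.Series, dict[str, SOAFit]]:
    """Fit per-level coefficients on a cohort, then apply them.

    Returns the coefficients, the per-record SOA areas, and the full
    per-level fit details (coefficient, standard error, n).  With
    ``mean_match`` the per-level paired t-statistic of SOA vs measurement
    is exactly 0 by construction.
    """
    if approximations is None:
        approximations = approximate_cohort(cohort)
    fits: dict[str, SOAFit] = {}
    for lvl in cohort.levels:
        try:
            fits[lvl] = fit_soa_coefficient(cohort, approximations, lvl, method)
        except FittingError as exc:
            raise FittingError(f"fitting failed at {lvl}: {exc}") from None
    coeffs = SOACoefficients({lvl: f.coefficient for lvl, f in fits.items()})
    soa = apply_soa(approximations, cohort.df["level"], coeffs)
    return coeffs, soa, fits
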