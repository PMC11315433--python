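"""Published reference statistics for the cervical central canal.

Per-level summary statistics from the normative CT cohort of 803 adults
(ages 18-35, levels C2-3 through C6-7) that this package's defaults are
calibrated against: means and standard deviations (mm^2) of the manually
traced canal area and of the three shape approximations, and the per-level
Pearson correlation between the approximations and the manual measurement.

These numbers parameterize the synthetic-cohort generator
(:mod:`canalarea.simulate`) and serve as fixed inputs when recomputing the
derived agreement tables; they are not produced by this package.
"""

from __future__ import annotations

from typing import NamedTuple

from .cohort import LEVELS

__all__ = ["MeanSD", "LevelSummary", "TABLE1", "CORRELATIONS", "LEVELS"]


class MeanSD(NamedTuple):
    """A mean and standard deviation pair, in mm^2."""

    mean: float
    sd: float


class LevelSummary(NamedTuple):
    """Per-level summary of manual measurement and shape approximations."""

    manual: MeanSD
    ellipse: MeanSD
    triangle: MeanSD
    rectangle: MeanSD


#: Per-level means +/- SD (mm^2) of the manual area measurement and of the
#: ellipse, triangle and rectangle approximations in the reference cohort.
TABLE1: dict[str, LevelSummary] = {
    "C2-3": LevelSummary(
        manual=MeanSD(280.72, 71.50),
        ellipse=MeanSD(257.54, 65.51),
        triangle=MeanSD(163.95, 41.70),
        rectangle=MeanSD(327.91, 83.41),
    ),
    "C3-4": LevelSummary(
        manual=MeanSD(257.49, 46.32),
        ellipse=MeanSD(242.93, 62.86),
        triangle=MeanSD(154.65, 40.02),
        rectangle=MeanSD(309.30, 80.03),
    ),
    "C4-5": LevelSummary(
        manual=MeanSD(265.99, 45.51),
        ellipse=MeanSD(252.55, 65.58),
        triangle=MeanSD(160.78, 41.75),
        rectangle=MeanSD(321.56, 83.50),
    ),
    "C5-6": LevelSummary(
        manual=MeanSD(273.83, 48.64),
        ellipse=MeanSD(262.49, 72.50),
        triangle=MeanSD(167.10, 46.15),
        rectangle=MeanSD(334.21, 92.31),
    ),
    "C6-7": LevelSummary(
        manual=MeanSD(271.38, 57.14),
        ellipse=MeanSD(263.86, 78.58),
        triangle=MeanSD(167.98, 50.03),
        rectangle=MeanSD(335.96, 100.05),
    ),
}

#: Per-level Pearson correlation between the shape approximations and the
#: manual measurement in the reference cohort.  A single value per level:
#: all three shapes are positive multiples of AP x IPD, and the Pearson
#: correlation is invariant under positive scaling.
CORRELATIONS: dict[str, float] = {
    "C2-3": 0.601,
    "C3-4": 0.575,
    "C4-5": 0.541,
    "C5-6": 0.624,
    "C6-7": 0.700,
}

#: Number of patients in the reference cohort.
COHORT_SIZE: int = 803
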