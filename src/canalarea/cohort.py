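"""Cohort data model and tabular I/O.

A cohort is a per-patient, per-vertebral-level table of three measurements
taken from cervical-spine CT: the anteroposterior (AP) diameter of the
central canal, the interpedicular distance (IPD), both in mm, and the
manually traced cross-sectional canal area in mm^2.  The on-disk format is
plain CSV with the header::

    patient_id,level,ap_diameter_mm,ipd_mm,measured_area_mm2

Units are baked into the column names; values use a ``.`` decimal point and
no thousands separators.  Level labels are stored canonically as ``C2-3``
... ``C6-7``; parsing is case-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

__all__ = [
    "LEVELS",
    "LEVEL_ORDER",
    "REQUIRED_COLUMNS",
    "MEASUREMENT_COLUMNS",
    "canonical_level",
    "Cohort",
    "read_cohort",
    "write_cohort",
]

#: Admissible vertebral levels, ordered cranial to caudal.
LEVELS: tuple[str, ...] = ("C2-3", "C3-4", "C4-5", "C5-6", "C6-7")

#: Cranial-to-caudal rank of each level.
LEVEL_ORDER: dict[str, int] = {lvl: i for i, lvl in enumerate(LEVELS)}

REQUIRED_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "level",
    "ap_diameter_mm",
    "ipd_mm",
    "measured_area_mm2",
)

#: The strictly positive numeric columns.
MEASUREMENT_COLUMNS: tuple[str, ...] = (
    "ap_diameter_mm",
    "ipd_mm",
    "measured_area_mm2",
)


def canonical_level(label: object) -> str:
    """Return the canonical form of a vertebral level label.

    Parsing is case-insensitive and whitespace-tolerant; the canonical forms
    are exactly the five members of :data:`LEVELS`.

    Raises
    ------
    ValidationError
        If the label is not one of the five cervical disc levels.
    """
    text = str(label).strip().upper()
    if text not in LEVEL_ORDER:
        raise ValidationError(
            f"unknown vertebral level {label!r}; expected one of {', '.join(LEVELS)}"
        )
    return text


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a raw measurement DataFrame.

    Returns a fresh frame with canonical column order, canonical level
    labels and float64 measurement columns.  Row numbering in error
    messages is 1-based over data rows.
    """
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")

    out = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    out = out.reset_index(drop=True)

    out["patient_id"] = out["patient_id"].astype(str)

    levels = []
    for i, raw in enumerate(out["level"]):
        try:
            levels.append(canonical_level(raw))
        except ValidationError as exc:
            raise ValidationError(f"row {i + 1}: {exc}") from None
    out["level"] = levels

    for col in MEASUREMENT_COLUMNS:
        values = pd.to_numeric(out[col], errors="coerce").astype(float)
        bad = ~np.isfinite(values) | (values <= 0.0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"row {row + 1}, field {col}: value {out[col].iloc[row]!r} "
                "is not a positive finite number"
            )
        out[col] = values

    dup = out.duplicated(subset=["patient_id", "level"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"row {row + 1}: duplicate (patient_id, level) pair "
            f"({out['patient_id'].iloc[row]!r}, {out['level'].iloc[row]!r})"
        )
    return out


@dataclass(frozen=True)
class Cohort:
    """A validated collection of per-patient, per-level measurements.

    Parameters
    ----------
    df : pandas.DataFrame
        One row per (patient, level) observation with the columns in
        :data:`REQUIRED_COLUMNS`.  Validated and canonicalized on
        construction; row order is preserved.
    provenance : str
        Free-text origin tag, e.g. ``"synthetic:seed=17"`` or a file path.
    """

    df: pd.DataFrame
    provenance: str = field(default="unspecified")

    def __post_init__(self) -> None:
        object.__setattr__(self, "df", _validate_frame(self.df))

    @classmethod
    def from_records(
        cls, records: list[tuple[str, str, float, float, float]], provenance: str = "records"
    ) -> "Cohort":
        """Build a cohort from (patient_id, level, ap, ipd, area) tuples."""
        return cls(pd.DataFrame(records, columns=list(REQUIRED_COLUMNS)), provenance)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def levels(self) -> list[str]:
        """Levels present, in cranial-to-caudal order."""
        present = set(self.df["level"])
        return [lvl for lvl in LEVELS if lvl in present]

    def level_mask(self, level: str) -> np.ndarray:
        """Boolean mask over records belonging to ``level``."""
        return (self.df["level"] == canonical_level(level)).to_numpy()

    def measured_area(self, level: str | None = None) -> np.ndarray:
        """Manually measured canal areas (mm^2), optionally for one level."""
        if level is None:
            return self.df["measured_area_mm2"].to_numpy()
        return self.df.loc[self.level_mask(level), "measured_area_mm2"].to_numpy()


def read_cohort(path: str | Path) -> Cohort:
    """Load a measurement CSV into a validated :class:`Cohort`.

    Every row either loads as a validated record or the whole load fails
    with an error naming the offending row and field; rows are never
    silently dropped.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=False)
    # keep_default_na=False keeps empty cells as '' so to_numeric flags them
    return Cohort(df, provenance=str(path))


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort to CSV at full stored precision.

    ``read_cohort(write_cohort(c, p))`` reproduces the records exactly.
    """
    path = Path(path)
    cohort.df.to_csv(path, index=False)
    return path
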