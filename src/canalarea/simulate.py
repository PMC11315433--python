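"""Synthetic-cohort generator.

Generates measurement cohorts with the statistical structure of the
803-patient normative reference population, so the full approximation and
evaluation pipeline can run with no external data.

Model per level
---------------
The downstream statistics depend on two quantities only: the product
``P = AP x IPD`` (every shape approximation is a positive multiple of it)
and the manually measured area.  The generator therefore targets

1. the moments of ``P`` — a lognormal matched by moments to the published
   rectangle-approximation mean and SD (the rectangle IS the product);
2. the moments of the measured area and its correlation with ``P`` —

   ``measured = m + r*s*z(P) + sqrt(1-r^2)*s*eps``

   where ``(m, s)`` are the target manual mean/SD, ``r`` the target Pearson
   correlation, ``z(P)`` the within-level standardized product and ``eps``
   unit normal noise, truncated below at 1 mm^2;
3. an invented split of ``P`` into IPD and AP through a lognormal ratio
   ``R = IPD/AP`` (the reference study reports no AP or IPD summaries, only
   areas): ``IPD = sqrt(P*R)``, ``AP = sqrt(P/R)``.  Every evaluation
   statistic is invariant to this split.

Generation is bit-stable for a fixed seed: one global seed spawns one
deterministic substream per level in cranial-to-caudal order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import published
from .cohort import LEVELS, Cohort, REQUIRED_COLUMNS, canonical_level
from .exceptions import ParameterError

__all__ = ["LevelSimParams", "SimConfig", "default_params", "generate_cohort"]

#: Lower truncation floor for generated measured areas, mm^2.
AREA_FLOOR: float = 1.0


@dataclass(frozen=True)
class LevelSimParams:
    """Simulation parameters for one vertebral level.

    Parameters
    ----------
    level : str
        Vertebral level label (``C2-3`` ... ``C6-7``).
    n : int
        Number of records to draw.
    manual_mean, manual_sd : float
        Target mean and SD of the manually measured area, mm^2.
    rect_mean, rect_sd : float
        Target mean and SD of the product AP x IPD (the rectangle
        approximation), mm^2.
    target_r : float
        Target Pearson correlation between the product and the measured
        area, in (0, 1].
    ratio_mean, ratio_cv : float
        Mean and coefficient of variation of the IPD/AP ratio used to split
        the product.  Cervical canals are wider than deep, hence the
        default mean of 2; the split does not affect any evaluation
        statistic.
    """

    level: str
    n: int = published.COHORT_SIZE
    manual_mean: float = 0.0
    manual_sd: float = 0.0
    rect_mean: float = 0.0
    rect_sd: float = 0.0
    target_r: float = 0.5
    ratio_mean: float = 2.0
    ratio_cv: float = 0.10

    def __post_init__(self) -> None:
        object.__setattr__(self, "level", canonical_level(self.level))
        if self.n < 0:
            raise ParameterError(f"{self.level}: n must be >= 0, got {self.n}")
        if self.n == 0:
            return
        for name in ("manual_mean", "manual_sd", "rect_mean", "rect_sd", "ratio_mean"):
            if getattr(self, name) <= 0.0:
                raise ParameterError(
                    f"{self.level}: {name} must be > 0, got {getattr(self, name)}"
                )
        if not 0.0 < self.target_r <= 1.0:
            raise ParameterError(
                f"{self.level}: target_r must be in (0, 1], got {self.target_r}"
            )
        if self.ratio_cv < 0.0:
            raise ParameterError(f"{self.level}: ratio_cv must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Full simulation configuration: one :class:`LevelSimParams` per level."""

    levels: tuple[LevelSimParams, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        seen = [p.level for p in self.levels]
        if len(set(seen)) != len(seen):
            raise ParameterError(f"duplicate level in config: {seen}")

    def params(self, level: str) -> LevelSimParams:
        level = canonical_level(level)
        for p in self.levels:
            if p.level == level:
                return p
        raise ParameterError(f"no parameters for level {level}")

    def to_dict(self) -> dict:
        return {"seed": self.seed, "levels": [asdict(p) for p in self.levels]}

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        levels = tuple(LevelSimParams(**p) for p in data["levels"])
        return cls(levels=levels, seed=int(data.get("seed", 0)))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_params(seed: int = 0, n: int | None = None) -> SimConfig:
    """Simulation configuration calibrated to the reference cohort.

    Per level: manual and rectangle (product) moments from the published
    summary table, target correlation from the published correlation table,
    ``n = 803`` records.  ``n`` can be overridden uniformly, e.g. for quick
    smoke runs or large-sample convergence checks.
    """
    levels = []
    for lvl in LEVELS:
        row = published.TABLE1[lvl]
        levels.append(
            LevelSimParams(
                level=lvl,
                n=published.COHORT_SIZE if n is None else n,
                manual_mean=row.manual.mean,
                manual_sd=row.manual.sd,
                rect_mean=row.rectangle.mean,
                rect_sd=row.rectangle.sd,
                target_r=published.CORRELATIONS[lvl],
            )
        )
    return SimConfig(levels=tuple(levels), seed=seed)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    if mean <= 0.0:
        raise ParameterError(f"lognormal mean must be > 0, got {mean}")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _draw_level(params: LevelSimParams, rng: np.random.Generator) -> pd.DataFrame:
    n = params.n
    mu_p, sig_p = _lognormal_params(params.rect_mean, params.rect_sd)
    product = rng.lognormal(mu_p, sig_p, size=n)

    mu_r, sig_r = _lognormal_params(
        params.ratio_mean, params.ratio_cv * params.ratio_mean
    )
    ratio = rng.lognormal(mu_r, sig_r, size=n)

    eps = rng.standard_normal(size=n)

    ipd = np.sqrt(product * ratio)
    ap = np.sqrt(product / ratio)

    if n >= 2 and product.std(ddof=1) > 0.0:
        z = (product - product.mean()) / product.std(ddof=1)
    else:
        z = np.zeros(n)
    r = params.target_r
    measured = (
        params.manual_mean
        + r * params.manual_sd * z
        + math.sqrt(max(0.0, 1.0 - r * r)) * params.manual_sd * eps
    )
    measured = np.maximum(measured, AREA_FLOOR)

    return pd.DataFrame(
        {
            "patient_id": [f"S{i + 1:05d}" for i in range(n)],
            "level": params.level,
            "ap_diameter_mm": ap,
            "ipd_mm": ipd,
            "measured_area_mm2": measured,
        }
    )


def generate_cohort(config: SimConfig) -> Cohort:
    """Draw a synthetic cohort. Deterministic given ``config.seed``.

    Per-level substreams are spawned from the global seed in
    cranial-to-caudal level order, so adding or resizing one level does not
    perturb the draws of another.
    """
    ordered = sorted(config.levels, key=lambda p: LEVELS.index(p.level))
    streams = np.random.SeedSequence(config.seed).spawn(len(ordered))
    frames = [
        _draw_level(p, np.random.default_rng(ss)) for p, ss in zip(ordered, streams)
    ]
    frames = [f for f in frames if len(f)]
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    return Cohort(df, provenance=f"synthetic:seed={config.seed}")
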