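"""Agreement statistics between approximations and manual measurements.

The machinery behind the per-level evaluation tables: mean difference of
paired areas, percent error, Pearson correlation with the weak/moderate/
strong banding used in the spinal morphometry literature, and the paired
sample t-test (two-sided, alpha 0.05).  Sample statistics use the n-1
denominator throughout.
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, canonical_level
from .shapes import APPROXIMATIONS

__all__ = [
    "mean_difference",
    "percent_error",
    "pearson_r",
    "correlation_band",
    "paired_t_test",
    "mean_difference_ci",
    "evaluate_level",
    "evaluate_cohort",
]

PercentErrorMode = Literal["of_means", "mean_of_ratios"]


def _paired(approx, measured) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(approx, dtype=float)
    m = np.asarray(measured, dtype=float)
    if a.shape != m.shape or a.ndim != 1:
        raise ValueError(
            f"approx and measured must be 1-d and positionally paired; "
            f"got shapes {a.shape} and {m.shape}"
        )
    if len(a) == 0:
        raise ValueError("need at least one pair")
    return a, m


def mean_difference(approx, measured) -> tuple[float, float]:
    """Mean and sample SD of the paired differences (approx - measured), mm^2.

    Sign convention is approximation minus manual measurement, so an
    approximation that underestimates (the ellipse, the triangle) has a
    negative mean difference.  SD is 0.0 for a single pair.
    """
    a, m = _paired(approx, measured)
    d = a - m
    sd = float(d.std(ddof=1)) if len(d) >= 2 else 0.0
    return float(d.mean()), sd


def percent_error(approx, measured, mode: PercentErrorMode = "of_means") -> float:
    """Signed percent error of the approximation, in %.

    ``of_means`` (default): ``100 * (mean(approx) - mean(measured)) / mean(measured)``
    — the relative error of the level means, the definition under which the
    published per-shape percent-error table is exactly recomputable from the
    published level means.

    ``mean_of_ratios``: mean of the per-record relative errors
    ``100 * (a - m) / m``.  Larger in magnitude whenever the per-record
    errors and 1/m covary; offered because per-record averaging is the other
    common reading of "percent error" for paired data.
    """
    a, m = _paired(approx, measured)
    if np.any(m <= 0.0):
        raise ValueError("measured areas must be strictly positive")
    if mode == "of_means":
        return float(100.0 * (a.mean() - m.mean()) / m.mean())
    if mode == "mean_of_ratios":
        return float(np.mean(100.0 * (a - m) / m))
    raise ValueError(f"unknown percent-error mode {mode!r}")


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient.

    Requires at least 3 pairs and nonzero variance in both vectors.
    """
    x, y = _paired(x, y)
    if len(x) < 3:
        raise ValueError("Pearson correlation needs at least 3 pairs")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def correlation_band(r: float) -> str:
    """Classify |r| as weak [0, 0.4), moderate [0.4, 0.7) or strong [0.7, 1]."""
    a = abs(r)
    if not a <= 1.0:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if a < 0.4:
        return "weak"
    if a < 0.7:
        return "moderate"
    return "strong"


def paired_t_test(x, y) -> tuple[float, float, int]:
    """Two-sided paired sample t-test of mean(x - y) = 0.

    Returns ``(t, p, n)`` with ``t = mean(d) / (sd(d)/sqrt(n))`` on the
    differences ``d = x - y`` and p from the t distribution with n-1 df.

    Degenerate cases are resolved by convention: identical pairs (all
    differences zero) give ``t = 0, p = 1``; zero-variance nonzero
    differences give ``t = +/-inf, p = 0``.
    """
    x, y = _paired(x, y)
    n = len(x)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, 1.0, n
        return math.copysign(math.inf, d.mean()), 0.0, n
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue), n


def mean_difference_ci(
    approx, measured, confidence: float = 0.95
) -> tuple[float, float]:
    """Two-sided t confidence interval for the mean paired difference, mm^2."""
    a, m = _paired(approx, measured)
    n = len(a)
    if n < 2:
        raise ValueError("confidence interval needs at least 2 pairs")
    d = a - m
    se = d.std(ddof=1) / math.sqrt(n)
    half = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1) * se
    return float(d.mean() - half), float(d.mean() + half)


def _evaluate_one(
    name: str, level: str, approx: np.ndarray, measured: np.ndarray
) -> dict:
    md, md_sd = mean_difference(approx, measured)
    lo, hi = mean_difference_ci(approx, measured)
    t, p, n = paired_t_test(approx, measured)
    r = pearson_r(approx, measured)
    return {
        "level": level,
        "approximation": name,
        "n": n,
        "mean_difference": md,
        "sd_difference": md_sd,
        "ci95_low": lo,
        "ci95_high": hi,
        "percent_error": percent_error(approx, measured, "of_means"),
        "percent_error_mean_of_ratios": percent_error(
            approx, measured, "mean_of_ratios"
        ),
        "pearson_r": r,
        "correlation_band": correlation_band(r),
        "t_statistic": t,
        "p_value": p,
    }


def evaluate_level(
    cohort: Cohort,
    approximations: pd.DataFrame,
    level: str,
    soa: pd.Series | None = None,
) -> pd.DataFrame:
    """Evaluate every approximation against the manual measurement at a level.

    Parameters
    ----------
    cohort : Cohort
        The measurement data.
    approximations : pandas.DataFrame
        Output of :func:`canalarea.shapes.approximate_cohort`, aligned to
        ``cohort.df``.
    level : str
        Vertebral level to evaluate.
    soa : pandas.Series, optional
        Per-record second-order approximation areas aligned to
        ``cohort.df``; adds a fourth row when given.

    Returns
    -------
    pandas.DataFrame
        One row per approximation with mean difference +/- SD, 95% CI,
        percent error (both definitions), Pearson r with its band, and the
        paired t-test.
    """
    level = canonical_level(level)
    mask = cohort.level_mask(level)
    if not mask.any():
        raise ValueError(f"no records at level {level}")
    measured = cohort.df.loc[mask, "measured_area_mm2"].to_numpy()

    rows = []
    for name in APPROXIMATIONS:
        rows.append(
            _evaluate_one(name, level, approximations.loc[mask, name].to_numpy(), measured)
        )
    if soa is not None:
        rows.append(_evaluate_one("soa", level, soa.loc[mask].to_numpy(), measured))
    return pd.DataFrame(rows)


def evaluate_cohort(
    cohort: Cohort,
    approximations: pd.DataFrame,
    soa: pd.Series | None = None,
) -> pd.DataFrame:
    """Concatenate :func:`evaluate_level` over all levels present, in order."""
    parts = [
        evaluate_level(cohort, approximations, lvl, soa=soa) for lvl in cohort.levels
    ]
    if not parts:
        raise ValueError("cohort has no records")
    return pd.concat(parts, ignore_index=True)
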