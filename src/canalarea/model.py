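"""Model/results interface tying the pipeline together.

:class:`CanalAreaModel` wraps a measurement cohort; ``fit()`` estimates the
per-level second-order approximation coefficients and returns a
:class:`CanalAreaResults` carrying the estimates, their standard errors,
the per-record approximations and the full per-level agreement statistics,
with a ``summary()`` table in the style of the statistical-modelling
packages this interface imitates.
"""

from __future__ import annotations

from io import StringIO
from pathlib import Path

import pandas as pd

from .cohort import Cohort, read_cohort
from .evaluation import evaluate_cohort
from .shapes import approximate_cohort
from .soa import (
    FitMethod,
    SOACoefficients,
    SOAFit,
    apply_soa,
    builtin_coefficients,
    fitted_soa_pipeline,
)

__all__ = ["CanalAreaModel", "CanalAreaResults"]


class CanalAreaModel:
    """Shape-approximation model of cervical canal area for one cohort.

    Parameters
    ----------
    cohort : Cohort
        Validated measurement data (see :class:`canalarea.cohort.Cohort`).

    Examples
    --------
    >>> from canalarea import CanalAreaModel
    >>> model = CanalAreaModel.simulate(seed=17)
    >>> res = model.fit(method="least_squares")
    >>> 0 < res.params["C6-7"] < 0.12
    True
    """

    def __init__(self, cohort: Cohort):
        self.cohort = cohort
        self.approximations = approximate_cohort(cohort)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CanalAreaModel":
        """Build a model from a measurement CSV file."""
        return cls(read_cohort(path))

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, provenance: str = "dataframe"
    ) -> "CanalAreaModel":
        """Build a model from an in-memory measurement DataFrame."""
        return cls(Cohort(df, provenance=provenance))

    @classmethod
    def simulate(cls, seed: int = 0, config=None) -> "CanalAreaModel":
        """Build a model on a synthetic cohort (see :mod:`canalarea.simulate`)."""
        from .simulate import default_params, generate_cohort

        if config is None:
            config = default_params(seed=seed)
        return cls(generate_cohort(config))

    def fit(self, method: FitMethod = "least_squares") -> "CanalAreaResults":
        """Fit per-level SOA coefficients and evaluate all approximations."""
        coeffs, soa, fits = fitted_soa_pipeline(
            self.cohort, method=method, approximations=self.approximations
        )
        return CanalAreaResults(self, coeffs, soa, fits, method=method)

    def results_with(self, coefficients: SOACoefficients) -> "CanalAreaResults":
        """Results under externally supplied coefficients (no fitting).

        Useful for applying the published built-in coefficients to new data.
        """
        soa = apply_soa(self.approximations, self.cohort.df["level"], coefficients)
        return CanalAreaResults(self, coefficients, soa, fits=None, method="fixed")

    def results_with_builtin(self) -> "CanalAreaResults":
        """Results under the published built-in coefficients."""
        return self.results_with(builtin_coefficients())


class CanalAreaResults:
    """Fit results: coefficients, uncertainties and agreement diagnostics.

    Attributes
    ----------
    params : pandas.Series
        Per-level rectangle weight ``c`` (ellipse weight fixed at 1).
    bse : pandas.Series
        Standard errors of the fitted weights (NaN when coefficients were
        supplied rather than fitted).
    soa_area : pandas.Series
        Per-record SOA area, aligned to the cohort.
    evaluation : pandas.DataFrame
        Per level x approximation agreement statistics (mean difference
        +/- SD, 95% CI, percent error, Pearson r, paired t-test).
    """

    def __init__(
        self,
        model: CanalAreaModel,
        coefficients: SOACoefficients,
        soa_area: pd.Series,
        fits: dict[str, SOAFit] | None,
        method: str,
    ):
        self.model = model
        self.coefficients = coefficients
        self.method = method
        self.soa_area = soa_area
        levels = model.cohort.levels
        self.params = pd.Series(
            {lvl: coefficients.for_level(lvl) for lvl in levels}, name="rect_weight"
        )
        self.bse = pd.Series(
            {lvl: (fits[lvl].stderr if fits else float("nan")) for lvl in levels},
            name="stderr",
        )
        self.evaluation = evaluate_cohort(
            model.cohort, model.approximations, soa=soa_area
        )

    @property
    def nobs(self) -> int:
        return len(self.model.cohort)

    def evaluation_for(self, approximation: str) -> pd.DataFrame:
        """Evaluation rows for one approximation across levels."""
        out = self.evaluation[self.evaluation["approximation"] == approximation]
        if out.empty:
            raise KeyError(f"unknown approximation {approximation!r}")
        return out.reset_index(drop=True)

    def summary(self) -> str:
        """Human-readable fit summary."""
        buf = StringIO()
        cohort = self.model.cohort
        buf.write("Cervical canal area approximation\n")
        buf.write("=" * 64 + "\n")
        buf.write(f"Records: {self.nobs:>6d}    Levels: {len(self.params)}\n")
        buf.write(f"Provenance: {cohort.provenance}\n")
        buf.write(f"SOA coefficient source: {self.method}\n\n")
        buf.write("Second-order approximation: soa = ellipse + c * rectangle\n")
        coef = pd.DataFrame({"c": self.params, "stderr": self.bse})
        buf.write(coef.to_string(float_format=lambda v: f"{v:.6g}") + "\n\n")
        soa_rows = self.evaluation[self.evaluation["approximation"] == "soa"]
        show = soa_rows[
            ["level", "mean_difference", "sd_difference", "pearson_r", "p_value"]
        ].rename(columns={"sd_difference": "sd", "mean_difference": "mean_diff"})
        buf.write("SOA vs manual measurement\n")
        buf.write(show.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        buf.write("\n")
        return buf.getvalue()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<CanalAreaResults method={self.method!r} nobs={self.nobs} "
            f"levels={list(self.params.index)}>"
        )
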