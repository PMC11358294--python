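"""Simple-linear-regression QSPR layer.

Regresses a physicochemical property on a single topological descriptor
with ordinary least squares and reports the statistics conventional in
QSPR tables: R (absolute Pearson correlation, with the slope's sign shown
in the model equation), R^2, RMSE and adjusted R^2.  RMSE defaults to the
residual standard error sqrt(SSE / (n - 2)) — the "Std. Error of the
Estimate" convention of mainstream statistics packages — with a flag for
the population form sqrt(SSE / n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PropertyTable",
    "RegressionFit",
    "DegeneratePredictorError",
    "fit_simple",
    "model_report",
    "rank_models",
]


class DegeneratePredictorError(ValueError):
    """The descriptor column is constant; the slope is unidentifiable."""


@dataclass(frozen=True)
class RegressionFit:
    """Statistics of a fitted simple OLS model y = intercept + slope * x."""

    intercept: float
    slope: float
    R: float
    R2: float
    RMSE: float
    adjR2: float
    n_obs: int

    def equation(self, prop: str, desc: str, sig: int = 4) -> str:
        b0 = float(f"{self.intercept:.{sig}g}")
        b1 = float(f"{self.slope:.{sig}g}")
        return f"{prop} = {b0:g} + {b1:g}*{desc}"


@dataclass(frozen=True)
class PropertyTable:
    """Compound-by-column table of properties and descriptors.

    ``data`` is indexed by unique compound name; ``properties`` and
    ``descriptors`` name the two column groups.  Missing values are NaN.
    """

    data: pd.DataFrame
    properties: tuple[str, ...]
    descriptors: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("compound names must be unique")
        for col in (*self.properties, *self.descriptors):
            if col not in self.data.columns:
                raise ValueError(f"column {col!r} missing from table")

    @classmethod
    def from_csv(
        cls,
        source,
        properties: Sequence[str],
        descriptors: Optional[Sequence[str]] = None,
    ) -> "PropertyTable":
        """Read ``compound,<prop...>,<desc...>`` CSV; empty cells are missing."""
        df = pd.read_csv(source, index_col=0)
        props = tuple(properties)
        descs = tuple(descriptors) if descriptors is not None else tuple(
            c for c in df.columns if c not in props
        )
        return cls(data=df, properties=props, descriptors=descs)

    def complete_pairs(self, prop: str, desc: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.data[[desc, prop]].dropna()
        return sub[desc].to_numpy(float), sub[prop].to_numpy(float)


def fit_simple(
    x: Sequence[float], y: Sequence[float], population_rmse: bool = False
) -> RegressionFit:
    """Ordinary least squares of y on x with QSPR-table statistics.

    R is reported as |Pearson r|; the slope carries the sign.  Requires at
    least three observations and a non-constant predictor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    n = x.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.ptp(x) == 0:
        raise DegeneratePredictorError("constant descriptor column")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    sse = float(res.ssr)
    r2 = float(res.rsquared)
    dof = n if population_rmse else n - 2
    rmse = math.sqrt(sse / dof)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionFit(
        intercept=float(intercept),
        slope=float(slope),
        R=math.sqrt(max(r2, 0.0)),
        R2=r2,
        RMSE=rmse,
        adjR2=adj,
        n_obs=n,
    )


@dataclass(frozen=True)
class ModelRow:
    """One fitted property-vs-descriptor model, or an explicit skip."""

    property: str
    descriptor: str
    fit: Optional[RegressionFit]
    equation: str = ""
    skipped: bool = False
    reason: str = ""


def model_report(table: PropertyTable, prop: str, desc: str) -> ModelRow:
    """Fit one property on one descriptor; insufficient or degenerate data
    yields an explicit skip record rather than an exception."""
    x, y = table.complete_pairs(prop, desc)
    if x.shape[0] < 3:
        return ModelRow(prop, desc, None, skipped=True,
                        reason=f"only {x.shape[0]} complete pairs")
    try:
        fit = fit_simple(x, y)
    except DegeneratePredictorError as exc:
        return ModelRow(prop, desc, None, skipped=True, reason=str(exc))
    return ModelRow(prop, desc, fit, equation=fit.equation(prop, desc))


def rank_models(table: PropertyTable, threshold_R: float = 0.850) -> list[ModelRow]:
    """All property x descriptor fits with R above threshold, best first."""
    rows = [
        model_report(table, prop, desc)
        for prop in table.properties
        for desc in table.descriptors
    ]
    kept = [r for r in rows if not r.skipped and r.fit.R > threshold_R]
    return sorted(kept, key=lambda r: (-r.fit.R, r.property, r.descriptor))
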