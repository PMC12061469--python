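"""Temperature regression and linear correction to a reference temperature.

Each parameter's individual means are regressed on recording air
temperature (ordinary least squares).  Parameters with a significant
slope are shifted to a common reference temperature:

    value_corrected = value - b * (T - T_ref)

Pulse number is exempt from correction regardless of its fitted slope.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidParameterError, UndefinedStatisticError
from .types import PARAMETER_NAMES

__all__ = [
    "TemperatureModel",
    "fit_temperature_regression",
    "temperature_correct",
    "reference_temperature",
    "fit_models",
    "apply_correction",
    "models_to_frame",
    "DEFAULT_EXEMPT",
]

#: Parameters never temperature-corrected.
DEFAULT_EXEMPT: frozenset[str] = frozenset({"pulse_number"})

DEFAULT_REFERENCE_C = 27.6


@dataclass(frozen=True)
class TemperatureModel:
    """OLS fit of one parameter against temperature."""

    parameter: str
    slope_b: float
    intercept: float
    slope_p_value: float
    r_squared: float
    n: int
    reference_temperature_c: float = DEFAULT_REFERENCE_C
    corrected: bool = False


def fit_temperature_regression(individual_means, temperatures_c,
                               parameter: str = "",
                               reference_temperature_c: float = DEFAULT_REFERENCE_C,
                               alpha: float = 0.05,
                               exempt: bool = False) -> TemperatureModel:
    """OLS of per-individual parameter means on recording temperature.

    ``corrected`` is set when the two-sided slope p-value is below
    ``alpha`` and the parameter is not exempt.
    """
    y = np.asarray(individual_means, dtype=float)
    t = np.asarray(temperatures_c, dtype=float)
    if y.size != t.size:
        raise InvalidParameterError("values and temperatures must align")
    if y.size < 3:
        raise InsufficientDataError(f"regression needs >= 3 pairs, got {y.size}")
    if np.ptp(t) == 0.0:
        raise UndefinedStatisticError("constant temperature: slope unidentifiable")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.linregress(t, y)
    p = float(res.pvalue)
    if not np.isfinite(p):  # zero residual variance: exact fit or constant y
        p = 0.0 if res.slope != 0.0 else 1.0
    corrected = bool(p < alpha) and not exempt
    return TemperatureModel(
        parameter=parameter,
        slope_b=float(res.slope),
        intercept=float(res.intercept),
        slope_p_value=p,
        r_squared=float(res.rvalue) ** 2 if np.isfinite(res.rvalue) else 0.0,
        n=int(y.size),
        reference_temperature_c=reference_temperature_c,
        corrected=corrected,
    )


def temperature_correct(value: float, temp_c: float,
                        model: TemperatureModel) -> float:
    """Shift a value to the reference temperature along the fitted slope.

    Identity when the model is not flagged for correction.
    """
    if not model.corrected:
        return value
    return value - model.slope_b * (temp_c - model.reference_temperature_c)


def reference_temperature(metadata: pd.DataFrame) -> float:
    """Mean recording temperature across individuals, to one decimal.

    ``metadata`` has one row per individual with a ``temperature_c``
    column (equivalently, locality temperatures weighted by how many
    males each locality contributed).
    """
    if "temperature_c" not in metadata.columns:
        raise InvalidParameterError("metadata lacks a temperature_c column")
    temps = pd.to_numeric(metadata["temperature_c"], errors="coerce")
    missing = metadata.loc[temps.isna()]
    if len(missing):
        ids = (missing["individual_id"].tolist()
               if "individual_id" in missing.columns else list(missing.index))
        raise InvalidParameterError(f"missing temperatures for: {ids}")
    return round(float(temps.mean()), 1)


def fit_models(ind_table: pd.DataFrame,
               parameters: tuple[str, ...] = PARAMETER_NAMES,
               reference_temperature_c: float | None = None,
               alpha: float = 0.05,
               exempt: frozenset[str] = DEFAULT_EXEMPT,
               ) -> dict[str, TemperatureModel]:
    """Fit one temperature model per parameter on an individual-means
    table (columns: the parameters plus ``temperature_c``).

    ``reference_temperature_c=None`` uses the table's own mean
    temperature (rounded to one decimal).
    """
    if reference_temperature_c is None:
        reference_temperature_c = reference_temperature(ind_table)
    models: dict[str, TemperatureModel] = {}
    for parameter in parameters:
        if parameter not in ind_table.columns:
            continue
        models[parameter] = fit_temperature_regression(
            ind_table[parameter], ind_table["temperature_c"],
            parameter=parameter,
            reference_temperature_c=reference_temperature_c,
            alpha=alpha, exempt=parameter in exempt,
        )
    return models


def apply_correction(ind_table: pd.DataFrame,
                     models: dict[str, TemperatureModel]) -> pd.DataFrame:
    """Return a copy with every corrected parameter shifted to the
    reference temperature; exempt/non-significant columns pass through."""
    out = ind_table.copy()
    temps = out["temperature_c"].to_numpy(dtype=float)
    for parameter, model in models.items():
        if model.corrected:
            out[parameter] = (
                out[parameter].to_numpy(dtype=float)
                - model.slope_b * (temps - model.reference_temperature_c)
            )
    return out


def models_to_frame(models: dict[str, TemperatureModel]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": m.parameter,
        "slope_b": m.slope_b,
        "intercept": m.intercept,
        "slope_p_value": m.slope_p_value,
        "r_squared": m.r_squared,
        "n": m.n,
        "reference_temperature_c": m.reference_temperature_c,
        "corrected": m.corrected,
    } for m in models.values()])
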