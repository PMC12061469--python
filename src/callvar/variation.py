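"""Four-level coefficient-of-variation framework with discriminability
scoring and random-effects one-way ANOVA.

Levels, each a CV = 100 * sample SD / mean:

* ``cv_i`` — per individual, over its calls;
* ``cv_p`` — per locality, over its individuals' means;
* ``cv_g`` — per group, over its individuals' means;
* ``cv_o`` — one value over all individual means.

A parameter is classified by its mean ``cv_i``: static (< 5%),
intermediate (5-12%, boundaries inclusive), or dynamic (> 12%).
Discriminability is reported both as ``cv_o / mean cv_i`` (the headline
ratio) and ``cv_o / mean cv_g``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidParameterError, UndefinedStatisticError
from .types import PARAMETER_NAMES

__all__ = [
    "cv_percent",
    "MultilevelCV",
    "multilevel_cv",
    "classify_cv",
    "discriminability_ratio",
    "AnovaResult",
    "model2_anova",
    "variation_table",
    "validate_measurement_table",
    "individual_means",
    "to_long",
]

LONG_COLUMNS = ("individual_id", "locality", "group", "parameter",
                "call_index", "value")


def cv_percent(values) -> float:
    """Coefficient of variation: 100 * sample SD (n-1) / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError(f"CV needs >= 2 values, got {v.size}")
    mean = v.mean()
    if mean == 0.0:
        raise UndefinedStatisticError("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


def _cv_or_nan(values) -> float:
    v = np.asarray(values, dtype=float)
    if v.size < 2 or v.mean() == 0.0:
        return float("nan")
    return float(100.0 * v.std(ddof=1) / v.mean())


def to_long(wide: pd.DataFrame, metadata: pd.DataFrame | None = None,
            parameters: tuple[str, ...] = PARAMETER_NAMES) -> pd.DataFrame:
    """Melt a per-call wide table (one row per call) to long format.

    ``metadata`` (one row per individual: individual_id, locality, group)
    is merged in when the wide table lacks those columns.
    """
    wide = wide.copy()
    if metadata is not None:
        meta_cols = [c for c in ("individual_id", "locality", "group")
                     if c in metadata.columns]
        wide = wide.drop(columns=[c for c in ("locality", "group")
                                  if c in wide.columns])
        wide = wide.merge(metadata[meta_cols], on="individual_id", how="left")
    missing = [c for c in ("individual_id", "locality", "group") if c not in wide]
    if missing:
        raise InvalidParameterError(f"missing metadata columns: {missing}")
    present = [p for p in parameters if p in wide.columns]
    if not present:  # non-canonical parameter columns: take everything else
        reserved = {"individual_id", "locality", "group", "call_index",
                    "snr_db", "latitude", "longitude", "temperature_c"}
        present = [c for c in wide.columns if c not in reserved]
    long = wide.melt(
        id_vars=["individual_id", "locality", "group", "call_index"],
        value_vars=present, var_name="parameter", value_name="value",
    )
    return long.dropna(subset=["value"]).reset_index(drop=True)


def validate_measurement_table(table: pd.DataFrame) -> None:
    """Check the long-table contract: required columns, a strict
    individual < locality < group hierarchy, >= 2 calls per individual
    per parameter."""
    missing = [c for c in LONG_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidParameterError(f"measurement table missing columns: {missing}")
    per_ind = table.groupby("individual_id")[["locality", "group"]].nunique()
    bad = per_ind[(per_ind["locality"] > 1) | (per_ind["group"] > 1)]
    if len(bad):
        raise InvalidParameterError(
            f"individuals mapped to multiple localities/groups: {list(bad.index)}"
        )
    per_loc = table.groupby("locality")["group"].nunique()
    if (per_loc > 1).any():
        raise InvalidParameterError(
            f"localities mapped to multiple groups: "
            f"{list(per_loc[per_loc > 1].index)}"
        )
    counts = table.groupby(["parameter", "individual_id"])["value"].count()
    short = counts[counts < 2]
    if len(short):
        raise InsufficientDataError(
            f"individuals with < 2 calls for a parameter: "
            f"{sorted({i for _, i in short.index})}"
        )


def individual_means(table: pd.DataFrame) -> pd.DataFrame:
    """Per-individual mean of each parameter (wide; locality/group kept)."""
    means = (table.groupby(["individual_id", "locality", "group", "parameter"])
             ["value"].mean().unstack("parameter").reset_index())
    means.columns.name = None
    return means


@dataclass
class MultilevelCV:
    """All four CV levels for one parameter."""

    parameter: str
    cv_i: pd.Series          # indexed by individual_id
    cv_p: pd.Series          # indexed by locality (NaN if < 2 individuals)
    cv_g: pd.Series          # indexed by group
    cv_o: float

    def _summary(self, s: pd.Series) -> tuple[float, float, float]:
        v = s.dropna()
        if v.empty:
            return (float("nan"),) * 3
        return float(v.mean()), float(v.min()), float(v.max())

    @property
    def cv_i_summary(self) -> tuple[float, float, float]:
        return self._summary(self.cv_i)

    @property
    def cv_p_summary(self) -> tuple[float, float, float]:
        return self._summary(self.cv_p)

    @property
    def cv_g_summary(self) -> tuple[float, float, float]:
        return self._summary(self.cv_g)


def multilevel_cv(table: pd.DataFrame) -> dict[str, MultilevelCV]:
    """Compute the four CV levels for every parameter in a long table.

    Localities or groups with fewer than 2 individuals get a NaN CV and
    are excluded from level summaries (with a warning).
    """
    validate_measurement_table(table)
    out: dict[str, MultilevelCV] = {}
    for parameter, sub in table.groupby("parameter", sort=False):
        cv_i = sub.groupby("individual_id")["value"].apply(_cv_or_nan)
        means = sub.groupby(["individual_id", "locality", "group"])["value"].mean()
        means = means.reset_index()
        cv_p = means.groupby("locality")["value"].apply(_cv_or_nan)
        cv_g = means.groupby("group")["value"].apply(_cv_or_nan)
        for level, series in (("locality", cv_p), ("group", cv_g)):
            dropped = list(series[series.isna()].index)
            if dropped:
                warnings.warn(
                    f"{parameter}: {level} units with < 2 individuals "
                    f"excluded from CV summary: {dropped}"
                )
        cv_o = cv_percent(means["value"])
        out[str(parameter)] = MultilevelCV(str(parameter), cv_i, cv_p, cv_g, cv_o)
    return out


def classify_cv(cv_i_mean: float, static_below: float = 5.0,
                dynamic_above: float = 12.0) -> str:
    """Variability class from the mean within-individual CV.

    static: cv < static_below; intermediate: static_below <= cv <=
    dynamic_above (both boundaries inclusive); dynamic: cv > dynamic_above.
    """
    if not np.isfinite(cv_i_mean) or cv_i_mean < 0:
        raise InvalidParameterError(f"cv must be a non-negative real, got {cv_i_mean}")
    if not 0 < static_below < dynamic_above:
        raise InvalidParameterError("thresholds must satisfy 0 < static < dynamic")
    if cv_i_mean < static_below:
        return "static"
    if cv_i_mean <= dynamic_above:
        return "intermediate"
    return "dynamic"


def discriminability_ratio(cv_o: float, cv_i_mean: float, cv_g_mean: float,
                           ) -> tuple[float | None, float | None]:
    """Overall-to-within ratios (cv_o/cv_i_mean, cv_o/cv_g_mean).

    A zero denominator yields None for that ratio, with a warning.
    """
    ratios: list[float | None] = []
    for name, denom in (("cv_i_mean", cv_i_mean), ("cv_g_mean", cv_g_mean)):
        if denom == 0.0 or not np.isfinite(denom):
            warnings.warn(f"discriminability ratio undefined: {name} = {denom}")
            ratios.append(None)
        else:
            ratios.append(cv_o / denom)
    return ratios[0], ratios[1]


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    eta_squared: float
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int


def model2_anova(values, labels) -> AnovaResult:
    """One-way random-effects ANOVA on individual means by group.

    Computed from sums of squares directly (F, p, and eta^2 coincide
    with the fixed-effects one-way layout).  eta^2 = SS_between /
    SS_total.  A zero total sum of squares degenerates to eta^2 = 0,
    p = 1 with a warning.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    if v.shape != lab.shape:
        raise InvalidParameterError("values and labels must have equal length")
    groups = [v[lab == g] for g in pd.unique(lab)]
    if len(groups) < 2:
        raise InsufficientDataError("ANOVA needs >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise InsufficientDataError("every group needs >= 2 individuals")
    grand = v.mean()
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    ss_total = ss_between + ss_within
    df_between = len(groups) - 1
    df_within = v.size - len(groups)
    if ss_total == 0.0:
        warnings.warn("ANOVA degenerate: zero total sum of squares")
        return AnovaResult(0.0, 1.0, 0.0, 0.0, 0.0, df_between, df_within)
    if ss_within == 0.0:
        return AnovaResult(float("inf"), 0.0, 1.0, ss_between, 0.0,
                           df_between, df_within)
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(float(f), p, ss_between / ss_total,
                       ss_between, ss_within, df_between, df_within)


def variation_table(table: pd.DataFrame,
                    thresholds: tuple[float, float] = (5.0, 12.0),
                    parameters: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Per-parameter variation summary: mean/SD/range over individual
    means, the four CV levels, both discriminability ratios, the
    variability class, and the group ANOVA."""
    levels = multilevel_cv(table)
    order = [p for p in (parameters or PARAMETER_NAMES) if p in levels]
    order += [p for p in levels if p not in order]
    ind = individual_means(table)
    rows = []
    for parameter in order:
        lv = levels[parameter]
        vals = ind[parameter].to_numpy(dtype=float)
        cv_i_mean, cv_i_lo, cv_i_hi = lv.cv_i_summary
        cv_p_mean, cv_p_lo, cv_p_hi = lv.cv_p_summary
        cv_g_mean, cv_g_lo, cv_g_hi = lv.cv_g_summary
        ratio_i, ratio_g = discriminability_ratio(lv.cv_o, cv_i_mean, cv_g_mean)
        anova = model2_anova(vals, ind["group"].to_numpy())
        rows.append({
            "parameter": parameter,
            "mean": vals.mean(),
            "sd": vals.std(ddof=1),
            "range_low": vals.min(),
            "range_high": vals.max(),
            "cv_i_mean": cv_i_mean, "cv_i_low": cv_i_lo, "cv_i_high": cv_i_hi,
            "cv_p_mean": cv_p_mean, "cv_p_low": cv_p_lo, "cv_p_high": cv_p_hi,
            "cv_g_mean": cv_g_mean, "cv_g_low": cv_g_lo, "cv_g_high": cv_g_hi,
            "cv_o": lv.cv_o,
            "ratio_o_over_i": ratio_i,
            "ratio_o_over_g": ratio_g,
            "classification": classify_cv(cv_i_mean, *thresholds),
            "anova_f": anova.f_statistic,
            "anova_p": anova.p_value,
            "eta_squared": anova.eta_squared,
        })
    return pd.DataFrame(rows)
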