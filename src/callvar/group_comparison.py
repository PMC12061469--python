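"""Distribution-driven two-group comparison with KDE summaries.

Per parameter: Shapiro-Wilk normality in each group decides the branch.
Both normal -> Bartlett homogeneity check + Student t-test; otherwise
-> Levene (median-centered) + Wilcoxon rank-sum (Mann-Whitney U,
exact for small tie-free samples, normal approximation with tie
correction otherwise).  Homogeneity failure is flagged, not fatal.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidParameterError, UndefinedStatisticError
from .types import PARAMETER_NAMES

__all__ = [
    "TestDecision",
    "choose_test",
    "GroupComparisonRow",
    "compare_groups",
    "KDESummary",
    "kde_summary",
    "kde_overlap",
]

EXACT_WILCOXON_MAX_N = 20


@dataclass(frozen=True)
class TestDecision:
    normality_p_a: float
    normality_p_b: float
    homogeneity_test: str       # "bartlett" | "levene"
    homogeneity_p: float
    homogeneity_ok: bool
    chosen_test: str            # "t-test" | "wilcoxon"


def _shapiro_p(values: np.ndarray) -> float:
    """Shapiro-Wilk p; NaN (non-normal branch) for constant samples."""
    if np.ptp(values) == 0.0:
        warnings.warn("constant sample: normality undefined, "
                      "falling back to the rank-based branch")
        return float("nan")
    return float(stats.shapiro(values).pvalue)


def choose_test(values_a, values_b, alpha: float = 0.05) -> TestDecision:
    """Select the comparison test from per-group normality.

    Both Shapiro-Wilk p-values > alpha -> Bartlett + t-test; any
    failure (or an undefined test on a constant sample) -> Levene +
    Wilcoxon.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("each group needs >= 3 values")
    p_a = _shapiro_p(a)
    p_b = _shapiro_p(b)
    normal = (p_a > alpha) and (p_b > alpha)  # NaN compares False
    if normal:
        homogeneity_test = "bartlett"
        hom_p = float(stats.bartlett(a, b).pvalue)
        chosen = "t-test"
    else:
        homogeneity_test = "levene"
        if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
            hom_p = 1.0
        else:
            hom_p = float(stats.levene(a, b, center="median").pvalue)
        chosen = "wilcoxon"
    ok = hom_p > alpha
    if not ok:
        warnings.warn(f"variance homogeneity rejected ({homogeneity_test} "
                      f"p={hom_p:.4g}); comparison proceeds, flagged")
    return TestDecision(p_a, p_b, homogeneity_test, hom_p, ok, chosen)


def _wilcoxon_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p: exact when both n <= 20 and tie-free."""
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    exact_ok = (max(a.size, b.size) <= EXACT_WILCOXON_MAX_N) and not has_ties
    method = "exact" if exact_ok else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


@dataclass(frozen=True)
class GroupComparisonRow:
    parameter: str
    mean_a: float
    mean_b: float
    normality_p_a: float
    normality_p_b: float
    homogeneity_test: str
    homogeneity_p: float
    chosen_test: str
    p_value: float
    significant: bool


def compare_groups(ind_table: pd.DataFrame,
                   group_order: tuple[str, str] | None = None,
                   parameters: tuple[str, ...] = PARAMETER_NAMES,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Compare two groups on every parameter of an individual-means
    table (columns: the parameters plus ``group``).

    Returns one row per parameter with means, the decision trail, and
    the two-sided p-value.
    """
    if "group" not in ind_table.columns:
        raise InvalidParameterError("table lacks a 'group' column")
    groups = list(pd.unique(ind_table["group"]))
    if group_order is not None:
        if set(group_order) != set(groups):
            raise InvalidParameterError(
                f"group_order {group_order} does not match data groups {groups}"
            )
        groups = list(group_order)
    if len(groups) != 2:
        raise InvalidParameterError(f"exactly 2 groups required, got {groups}")
    ga, gb = groups
    rows = []
    for parameter in parameters:
        if parameter not in ind_table.columns:
            continue
        a = ind_table.loc[ind_table["group"] == ga, parameter].to_numpy(float)
        b = ind_table.loc[ind_table["group"] == gb, parameter].to_numpy(float)
        if a.size < 2 or b.size < 2:
            raise InsufficientDataError(
                f"{parameter}: each group needs >= 2 individuals"
            )
        decision = choose_test(a, b, alpha=alpha)
        if decision.chosen_test == "t-test":
            p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        else:
            p = _wilcoxon_p(a, b)
        rows.append(GroupComparisonRow(
            parameter=parameter,
            mean_a=float(a.mean()), mean_b=float(b.mean()),
            normality_p_a=decision.normality_p_a,
            normality_p_b=decision.normality_p_b,
            homogeneity_test=decision.homogeneity_test,
            homogeneity_p=decision.homogeneity_p,
            chosen_test=decision.chosen_test,
            p_value=p,
            significant=p < alpha,
        ))
    frame = pd.DataFrame([r.__dict__ for r in rows])
    return frame.rename(columns={"mean_a": f"mean_{ga}", "mean_b": f"mean_{gb}",
                                 "normality_p_a": f"normality_p_{ga}",
                                 "normality_p_b": f"normality_p_{gb}"})


@dataclass(frozen=True)
class KDESummary:
    """Gaussian kernel density estimate evaluated on a grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def kde_summary(values, grid=None, n_grid: int = 256,
                pad_bandwidths: float = 4.0) -> KDESummary:
    """Gaussian KDE with Silverman bandwidth.

    The default grid spans the data padded by ``pad_bandwidths``
    bandwidths so the numeric integral is within 1% of 1.
    """
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < 2:
        raise UndefinedStatisticError("KDE needs >= 2 distinct values")
    kde = stats.gaussian_kde(v, bw_method="silverman")
    bandwidth = float(kde.factor * v.std(ddof=1))
    if grid is None:
        lo = v.min() - pad_bandwidths * bandwidth
        hi = v.max() + pad_bandwidths * bandwidth
        grid = np.linspace(lo, hi, n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
    return KDESummary(grid, kde(grid), bandwidth)


def kde_overlap(values_a, values_b, n_grid: int = 512) -> float:
    """Overlap coefficient: integral of the pointwise minimum of the
    two group densities (0 = disjoint, 1 = identical)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    ka = kde_summary(a, n_grid=n_grid)
    kb = kde_summary(b, n_grid=n_grid)
    lo = min(ka.grid.min(), kb.grid.min())
    hi = max(ka.grid.max(), kb.grid.max())
    grid = np.linspace(lo, hi, n_grid)
    da = kde_summary(a, grid=grid).density
    db = kde_summary(b, grid=grid).density
    return float(np.trapezoid(np.minimum(da, db), grid))
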