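"""Distance matrices over localities and Mantel permutation tests.

Geographic distances are great-circle (haversine, Earth radius
6371.0088 km).  The default acoustic distance between two localities is
the absolute difference of their mean parameter values; a multivariate
Euclidean option over standardized means is available.  The Mantel test
correlates upper-triangle entries and permutes the labels of one matrix
jointly over rows and columns; p is one-tailed upper by default with
the +1 identity-permutation correction.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidParameterError, UndefinedStatisticError

__all__ = [
    "DistanceMatrix",
    "haversine_matrix",
    "acoustic_distance_matrix",
    "multivariate_acoustic_distance",
    "MantelResult",
    "mantel_test",
    "mantel_table",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric non-negative matrix with ordered labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if v.shape != (n, n):
            raise InvalidParameterError(
                f"matrix shape {v.shape} does not match {n} labels"
            )
        if not np.allclose(v, v.T):
            raise InvalidParameterError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise InvalidParameterError("distance matrix diagonal must be zero")
        if (v < -1e-12).any():
            raise InvalidParameterError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries (row-major, excluding the diagonal)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance between two points in decimal degrees."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = (math.sin(dphi / 2) ** 2
         + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def haversine_matrix(coordinates, labels=None) -> DistanceMatrix:
    """Pairwise great-circle distances (km) from (lat, lon) pairs."""
    coords = list(coordinates)
    if labels is None:
        labels = [str(i) for i in range(len(coords))]
    labels = tuple(str(s) for s in labels)
    for label, (lat, lon) in zip(labels, coords):
        if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
            raise InvalidParameterError(
                f"invalid coordinates for {label!r}: ({lat}, {lon})"
            )
    n = len(coords)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_km(*coords[i], *coords[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


def acoustic_distance_matrix(population_means) -> DistanceMatrix:
    """|mean_i - mean_j| over localities, from a mapping or Series."""
    means = pd.Series(population_means, dtype=float)
    if means.isna().any():
        raise InvalidParameterError(
            f"missing locality means: {list(means[means.isna()].index)}"
        )
    v = means.to_numpy()
    values = np.abs(v[:, None] - v[None, :])
    return DistanceMatrix(tuple(str(s) for s in means.index), values)


def multivariate_acoustic_distance(means_by_locality: pd.DataFrame,
                                   ) -> DistanceMatrix:
    """Euclidean distance over z-standardized per-locality means
    (localities as rows, parameters as columns).  Non-default option."""
    z = (means_by_locality - means_by_locality.mean()) / means_by_locality.std(ddof=1)
    v = z.to_numpy(dtype=float)
    diff = v[:, None, :] - v[None, :, :]
    values = np.sqrt((diff ** 2).sum(axis=2))
    return DistanceMatrix(tuple(str(s) for s in means_by_locality.index), values)


@dataclass(frozen=True)
class MantelResult:
    parameter: str
    r: float
    p: float
    n_permutations: int
    seed: int | None
    method: str
    alternative: str


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))


def mantel_test(a: DistanceMatrix, b: DistanceMatrix,
                n_permutations: int = 9999, seed: int | None = None,
                alternative: str = "greater", method: str = "auto",
                parameter: str = "") -> MantelResult:
    """Mantel permutation test of association between two matrices.

    r is the Pearson correlation of upper-triangle entries.  Labels of
    matrix ``b`` are permuted jointly over rows and columns.  With
    ``method='auto'`` all n! relabelings are enumerated when n <= 5;
    otherwise ``n_permutations`` random permutations are drawn and p
    includes the +1 identity correction:
    p = (1 + #{r_perm >= r_obs}) / (1 + n_permutations).
    """
    if a.labels != b.labels:
        raise InvalidParameterError("distance matrices have different labels")
    n = a.n
    if n < 3:
        raise InsufficientDataError("Mantel test needs >= 3 localities")
    if alternative not in ("greater", "two-sided"):
        raise InvalidParameterError(f"unknown alternative {alternative!r}")
    x = a.condensed()
    y = b.condensed()
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedStatisticError("constant distance matrix: r undefined")
    r_obs = _pearson(x, y)
    iu = np.triu_indices(n, k=1)
    tol = 1e-12

    def extreme(r_perm: float) -> bool:
        if alternative == "greater":
            return r_perm >= r_obs - tol
        return abs(r_perm) >= abs(r_obs) - tol

    exhaustive = method == "exhaustive" or (method == "auto" and n <= 5)
    if exhaustive:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            bp = b.values[np.ix_(perm, perm)][iu]
            if extreme(_pearson(x, bp)):
                count += 1
            total += 1
        return MantelResult(parameter, r_obs, count / total, total, seed,
                            "exhaustive", alternative)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        bp = b.values[np.ix_(perm, perm)][iu]
        if extreme(_pearson(x, bp)):
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return MantelResult(parameter, r_obs, p, n_permutations, seed,
                        "sampled", alternative)


def mantel_table(geo: DistanceMatrix, locality_means: pd.DataFrame,
                 n_permutations: int = 9999, seed: int | None = None,
                 alternative: str = "greater",
                 method: str = "sampled") -> pd.DataFrame:
    """One Mantel test per parameter column of a locality-means table
    (indexed by locality, aligned to ``geo.labels``)."""
    means = locality_means.loc[list(geo.labels)]
    rows = []
    for parameter in means.columns:
        acoustic = acoustic_distance_matrix(means[parameter])
        res = mantel_test(geo, acoustic, n_permutations=n_permutations,
                          seed=seed, alternative=alternative,
                          method=method, parameter=str(parameter))
        rows.append({"parameter": res.parameter, "r": res.r, "p": res.p,
                     "n_permutations": res.n_permutations,
                     "seed": res.seed, "method": res.method})
    return pd.DataFrame(rows)
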