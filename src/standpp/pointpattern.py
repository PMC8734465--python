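"""Kernel estimators for marked spatial point-pattern statistics.

Three second-order summaries of a mapped tree pattern:

* the pair-correlation function ``g(r)`` — density of point pairs at
  separation r relative to complete spatial randomness (g > 1 clustering,
  g < 1 overdispersion);
* the univariate mark-correlation function ``kmm(r)`` — mean product of
  quantitative marks (dbh) of r-separated pairs normalised by the squared
  mean mark, < 1 where nearby trees are smaller than expected;
* Schlather's Moran's-I bivariate mark correlation ``I(r)`` — a
  correlation-type statistic in [-1, 1] of two patterns' centred,
  standardised marks at separation r.

All three use an Epanechnikov kernel in distance.  ``g(r)`` uses the
translation edge correction, which is exact for rectangular windows; the
two mark statistics are ratio estimators whose edge effects largely
cancel and carry no explicit correction.  Lags with no pairs inside the
kernel support return 0 (with a warning) rather than NaN so downstream
envelope machinery stays total.

For lags smaller than the bandwidth the kernel window is truncated at
zero distance, which biases ``g``; interpret curves at r >= h.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .census import Census, PlotWindow
from .errors import DomainError, EstimationError, StandppError

__all__ = [
    "MarkedPattern",
    "LagSpec",
    "EstimatorCurve",
    "pcf_estimate",
    "mark_correlation",
    "schlather_I",
]

log = logging.getLogger(__name__)


@dataclass
class MarkedPattern:
    """Points in a rectangular window, optionally with quantitative marks."""

    points: np.ndarray  # (n, 2) metres
    window: PlotWindow
    marks: np.ndarray | None = None  # (n,) finite floats, e.g. dbh in cm
    species: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not self.window.contains(self.points[:, 0], self.points[:, 1]).all():
            raise StandppError("points outside window")
        if self.marks is not None:
            self.marks = np.asarray(self.marks, dtype=float).ravel()
            if self.marks.shape[0] != self.points.shape[0]:
                raise StandppError("marks must align 1:1 with points")
            if not np.all(np.isfinite(self.marks)):
                raise StandppError("marks must be finite")
        if self.species is not None:
            self.species = np.asarray(self.species, dtype=object).ravel()
            if self.species.shape[0] != self.points.shape[0]:
                raise StandppError("species labels must align 1:1 with points")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @classmethod
    def from_census(cls, census: Census, species: str | Sequence[str] | None = None,
                    status: str = "live", per: str = "individual") -> "MarkedPattern":
        """Build a pattern from a census.

        ``per="individual"`` keeps one point per individual plant, located
        at its largest stem and marked with that stem's dbh (the default
        for spatial analysis); ``per="stem"`` keeps every stem.
        """
        sub = census.subset(species=species, status=status).table
        if per == "individual":
            sub = sub.sort_values("dbh", ascending=False) \
                     .drop_duplicates("individual_id").sort_index()
        elif per != "stem":
            raise DomainError(f"per must be 'individual' or 'stem', got {per!r}")
        return cls(points=sub[["x", "y"]].to_numpy(float), window=census.window,
                   marks=sub["dbh"].to_numpy(float),
                   species=sub["species_code"].to_numpy(object))


@dataclass(frozen=True)
class LagSpec:
    """Spatial lags and kernel settings for the estimators.

    ``r_values`` are the lags (m) at which curves are evaluated, ``h`` the
    Epanechnikov bandwidth (m).  Lags beyond half the shorter window side
    are refused unless ``allow_large_r`` is set.
    """

    r_values: tuple[float, ...] = tuple(float(r) for r in range(1, 51))
    h: float = 5.0
    edge_correction: str = "translation"
    allow_large_r: bool = False

    def __post_init__(self):
        r = np.asarray(self.r_values, dtype=float)
        if r.size == 0 or np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise DomainError("r_values must be positive and strictly increasing")
        if self.h <= 0:
            raise DomainError("bandwidth h must be positive")
        if self.edge_correction not in ("translation", "none"):
            raise DomainError(f"unknown edge correction {self.edge_correction!r}")
        object.__setattr__(self, "r_values", tuple(float(v) for v in r))

    @classmethod
    def mark_default(cls) -> "LagSpec":
        """Default lag grid for mark statistics: 1..150 m."""
        return cls(r_values=tuple(float(r) for r in range(1, 151)))

    def check_window(self, window: PlotWindow) -> None:
        rmax = max(self.r_values)
        half = min(window.width, window.height) / 2.0
        if rmax > half and not self.allow_large_r:
            raise DomainError(
                f"max lag {rmax} m exceeds half the shorter window side ({half} m); "
                "set allow_large_r to override")

    @property
    def r(self) -> np.ndarray:
        return np.asarray(self.r_values, dtype=float)


@dataclass
class EstimatorCurve:
    """A statistic evaluated over spatial lags."""

    statistic: str  # "g", "kmm" or "I"
    r: np.ndarray
    values: np.ndarray
    n_points: int
    n_pairs: np.ndarray | None = None  # pairs inside kernel support per lag
    mark_mean: float | None = None
    mark_sd: float | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"r": self.r, "value": self.values})
        if self.n_pairs is not None:
            out["n_pairs"] = self.n_pairs
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def _epanechnikov(u: np.ndarray, h: float) -> np.ndarray:
    """k_h(u) = 0.75/h * (1 - (u/h)^2) on |u| < h."""
    z = u / h
    out = 0.75 / h * (1.0 - z * z)
    return np.where(np.abs(z) < 1.0, out, 0.0)


def _within_pairs(pattern: MarkedPattern, rmax: float):
    """Unordered within-pattern pairs (i, j, d) with d <= rmax."""
    tree = cKDTree(pattern.points)
    pairs = tree.query_pairs(rmax, output_type="ndarray")
    if pairs.size == 0:
        return (np.empty(0, int), np.empty(0, int), np.empty(0, float))
    diff = pattern.points[pairs[:, 0]] - pattern.points[pairs[:, 1]]
    d = np.hypot(diff[:, 0], diff[:, 1])
    return pairs[:, 0], pairs[:, 1], d


def _cross_pairs(p1: MarkedPattern, p2: MarkedPattern, rmax: float, same: bool):
    """Cross pairs (i in p1, j in p2, d <= rmax); drops i==j when same."""
    tree1, tree2 = cKDTree(p1.points), cKDTree(p2.points)
    coo = tree1.sparse_distance_matrix(tree2, rmax, output_type="coo_matrix")
    i, j, d = coo.row, coo.col, coo.data
    if same:
        keep = i != j
        i, j, d = i[keep], j[keep], d[keep]
    return i, j, d


def _translation_weight(points: np.ndarray, i, j, window: PlotWindow) -> np.ndarray:
    """|W| / |W intersect W+z| for each pair displacement z (rectangular W)."""
    dx = np.abs(points[i, 0] - points[j, 0])
    dy = np.abs(points[i, 1] - points[j, 1])
    return window.area / ((window.width - dx) * (window.height - dy))


def pcf_estimate(pattern: MarkedPattern, spec: LagSpec = LagSpec()) -> EstimatorCurve:
    """Kernel estimate of the pair-correlation function g(r).

    ``g_hat(r) = sum_{i!=j} k_h(r - d_ij) w_ij / (lambda^2 |W| 2 pi r)``
    with Epanechnikov kernel ``k_h``, translation edge weights
    ``w_ij = |W| / |W ∩ W_z|`` and intensity ``lambda = n / |W|``.
    """
    if pattern.n < 2:
        raise EstimationError("pair correlation needs at least 2 points")
    spec.check_window(pattern.window)
    r = spec.r
    rmax = r[-1] + spec.h
    i, j, d = _within_pairs(pattern, rmax)
    if spec.edge_correction == "translation":
        w = _translation_weight(pattern.points, i, j, pattern.window)
    else:
        w = np.ones_like(d)
    n, area = pattern.n, pattern.window.area
    values = np.zeros_like(r)
    npairs = np.zeros_like(r, dtype=int)
    for k_idx, rk in enumerate(r):
        kern = _epanechnikov(rk - d, spec.h)
        sup = kern > 0
        npairs[k_idx] = int(np.count_nonzero(sup))
        if npairs[k_idx] == 0:
            log.warning("pcf: no pairs in kernel support at r=%.3g; returning 0", rk)
            continue
        # ordered-pair sum = 2 * unordered sum
        s = 2.0 * float(np.sum(kern[sup] * w[sup]))
        values[k_idx] = s * area / (n * n * 2.0 * np.pi * rk)
    return EstimatorCurve("g", r, values, n, npairs)


def mark_correlation(pattern: MarkedPattern, spec: LagSpec | None = None) -> EstimatorCurve:
    """Kernel estimate of the mark-correlation function kmm(r).

    The kernel-weighted mean mark product over r-separated pairs divided
    by the squared mean mark; 1 under independent marking, < 1 where
    close neighbours are smaller than expected.
    """
    if spec is None:
        spec = LagSpec.mark_default()
    if pattern.marks is None:
        raise EstimationError("mark correlation requires marks")
    if pattern.n < 2:
        raise EstimationError("mark correlation needs at least 2 points")
    spec.check_window(pattern.window)
    mu = float(np.mean(pattern.marks))
    if mu == 0.0:
        raise EstimationError("zero mean mark: kmm normalisation undefined")
    r = spec.r
    i, j, d = _within_pairs(pattern, r[-1] + spec.h)
    mm = pattern.marks[i] * pattern.marks[j]
    values, npairs = _ratio_curve(r, spec.h, d, mm, norm=mu * mu, name="kmm")
    return EstimatorCurve("kmm", r, values, pattern.n, npairs,
                          mark_mean=mu, mark_sd=float(np.std(pattern.marks)))


def schlather_I(focal: MarkedPattern, other: MarkedPattern,
                spec: LagSpec | None = None) -> EstimatorCurve:
    """Schlather's Moran's-I bivariate mark-correlation function.

    Kernel-weighted mean over cross pairs (i focal, j other) of
    ``(m1_i - mu1)(m2_j - mu2) / (sigma1 sigma2)`` with marginal mark
    moments; in [-1, 1] up to estimation noise.  When both arguments are
    the same pattern, self-pairs are excluded.
    """
    if spec is None:
        spec = LagSpec.mark_default()
    if focal.marks is None or other.marks is None:
        raise EstimationError("Schlather's I requires marks on both patterns")
    if focal.n == 0 or other.n == 0:
        raise EstimationError("Schlather's I requires non-empty patterns")
    spec.check_window(focal.window)
    mu1, mu2 = float(np.mean(focal.marks)), float(np.mean(other.marks))
    s1, s2 = float(np.std(focal.marks)), float(np.std(other.marks))
    if s1 == 0.0 or s2 == 0.0:
        raise EstimationError("zero mark variance: Schlather's I undefined")
    same = focal.n == other.n and np.array_equal(focal.points, other.points)
    r = spec.r
    i, j, d = _cross_pairs(focal, other, r[-1] + spec.h, same=same)
    prod = (focal.marks[i] - mu1) * (other.marks[j] - mu2)
    values, npairs = _ratio_curve(r, spec.h, d, prod, norm=s1 * s2, name="I")
    return EstimatorCurve("I", r, values, focal.n, npairs)


def _ratio_curve(r, h, d, numerator_terms, norm, name):
    """Shared kernel-ratio loop for the two mark statistics."""
    values = np.zeros_like(r)
    npairs = np.zeros_like(r, dtype=int)
    for k_idx, rk in enumerate(r):
        kern = _epanechnikov(rk - d, h)
        sup = kern > 0
        npairs[k_idx] = int(np.count_nonzero(sup))
        den = float(np.sum(kern[sup]))
        if den == 0.0:
            log.warning("%s: no pairs in kernel support at r=%.3g; returning 0",
                        name, rk)
            continue
        values[k_idx] = float(np.sum(kern[sup] * numerator_terms[sup])) / den / norm
    return values, npairs
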