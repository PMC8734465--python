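"""Predictor engineering and tree-ensemble permutation importance.

Builds per-tree predictor tables — sampled land-use/soil raster classes,
a focal-window abundance surface, and five 10-m neighbourhood features —
and ranks predictors of species abundance or dbh with an ensemble of
conditional-inference-style regression trees and out-of-bag permutation
importance.

The tree learner follows the conditional-inference recipe: at each node
every predictor's association with the response is scored by a
standardised linear statistic (correlation-type for continuous
predictors, one-way mean-contrast for categorical ones) with an
asymptotic p-value, Bonferroni-corrected across predictors; the node
splits on the most significant predictor at its variance-reduction
maximising cutpoint, and stops when no corrected p-value clears alpha.
Separating the stop decision (a multiplicity-corrected test) from the
cutpoint search is what removes the selection bias toward predictors
with many candidate split points when categorical and continuous
predictors are mixed.

Importance is the mean increase in out-of-bag squared prediction error
when one predictor's column is permuted, averaged over the ensemble
(default 500 tree iterations), i.e. the marginal loss of prediction
accuracy in response units squared.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import convolve2d
from scipy.spatial import cKDTree

from .census import Census, CovariateRaster, QuadratGrid
from .errors import ConfigurationError, DomainError, StandppError

__all__ = [
    "focal_abundance_surface",
    "sample_raster_at_points",
    "neighborhood_features",
    "build_feature_table",
    "CITree",
    "fit_citree",
    "ImportanceResult",
    "ensemble_importance",
]

NEIGHBOR_RADIUS = 10.0  # m, Table-style stand-feature neighbourhood
NEIGHBOR_COLUMNS = ("nbr_count", "nbr_mean_dbh", "nbr_cv_dbh",
                    "nbr_mean_dist", "nbr_cv_dist")


def focal_abundance_surface(census: Census, species: str | None = None,
                            cell_size: float = 20.0,
                            window_cells: int = 3) -> CovariateRaster:
    """Moving focal-window mean tree abundance on a grid.

    Counts stems per ``cell_size`` cell, then replaces each cell by the
    mean count over the ``window_cells`` x ``window_cells`` neighbourhood,
    truncated at the plot edges (mean over the cells that exist).
    """
    if window_cells < 1 or window_cells % 2 == 0:
        raise DomainError("focal window must be an odd positive cell count")
    sub = census.subset(species=species)
    grid = QuadratGrid.for_window(census.window, cell_size)
    counts = np.zeros((grid.n_rows, grid.n_cols))
    if sub.n_stems:
        from .census import assign_quadrats
        idx = assign_quadrats(sub, grid)
        np.add.at(counts, (idx[:, 1], idx[:, 0]), 1.0)
    kernel = np.ones((window_cells, window_cells))
    sums = convolve2d(counts, kernel, mode="same")
    norm = convolve2d(np.ones_like(counts), kernel, mode="same")
    return CovariateRaster(sums / norm, cell_size, census.window.origin,
                           kind="continuous")


def sample_raster_at_points(raster: CovariateRaster, points) -> np.ndarray:
    """Value of the cell containing each point (no interpolation).

    Points share the half-open cell convention of quadrat assignment;
    nodata cells yield NaN; points outside the extent raise.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    return raster.values_at(pts[:, 0], pts[:, 1])


def neighborhood_features(census: Census, radius: float = NEIGHBOR_RADIUS) -> pd.DataFrame:
    """Five neighbourhood features per tree, over other trees within ``radius``.

    Columns: neighbour count; mean and CV of neighbour dbh; mean and CV of
    neighbour distance (CV = sample sd / mean, ddof=1); plus ``border``
    (True when the tree stands closer than ``radius`` to a plot edge, so
    its neighbourhood is truncated).  Isolated trees get count 0 and NaN
    for the undefined features; CVs need at least two neighbours.
    """
    t = census.table
    pts = t[["x", "y"]].to_numpy(float)
    dbh = t["dbh"].to_numpy(float)
    n = len(pts)
    tree = cKDTree(pts)
    neighbors = tree.query_ball_point(pts, r=radius)
    out = np.full((n, 5), np.nan)
    for i, nbrs in enumerate(neighbors):
        nbrs = [j for j in nbrs if j != i]
        cnt = len(nbrs)
        out[i, 0] = cnt
        if cnt == 0:
            continue
        nd = dbh[nbrs]
        dist = np.hypot(pts[nbrs, 0] - pts[i, 0], pts[nbrs, 1] - pts[i, 1])
        out[i, 1] = nd.mean()
        out[i, 3] = dist.mean()
        if cnt >= 2:
            if out[i, 1] > 0:
                out[i, 2] = nd.std(ddof=1) / out[i, 1]
            if out[i, 3] > 0:
                out[i, 4] = dist.std(ddof=1) / out[i, 3]
    w = census.window
    edge_dist = np.minimum.reduce([
        pts[:, 0] - w.origin[0], w.xmax - pts[:, 0],
        pts[:, 1] - w.origin[1], w.ymax - pts[:, 1]])
    frame = pd.DataFrame(out, columns=list(NEIGHBOR_COLUMNS), index=t.index)
    frame["border"] = edge_dist < radius
    return frame


def build_feature_table(census: Census, species: str,
                        rasters: dict[str, CovariateRaster] | None = None,
                        radius: float = NEIGHBOR_RADIUS,
                        cell_size: float = 20.0,
                        drop_border: bool = False) -> pd.DataFrame:
    """One row per tree of ``species``: responses plus predictors.

    Responses: ``abundance`` (the species' focal-window abundance surface
    sampled at the tree) and ``dbh``.  Predictors: each named raster
    sampled at the tree (categorical rasters become pandas categoricals)
    and the five neighbourhood features computed over all trees in the
    census.  Border trees are flagged and kept unless ``drop_border``.
    """
    nbr = neighborhood_features(census, radius=radius)
    sub_mask = (census.table["species_code"] == species).to_numpy()
    if not sub_mask.any():
        raise StandppError(f"no stems of species {species!r}")
    rows = census.table.loc[sub_mask]
    pts = rows[["x", "y"]].to_numpy(float)
    surface = focal_abundance_surface(census, species, cell_size=cell_size)
    out = pd.DataFrame(index=rows.index)
    out["abundance"] = sample_raster_at_points(surface, pts)
    out["dbh"] = rows["dbh"].to_numpy(float)
    for name, raster in (rasters or {}).items():
        if raster.kind == "categorical" and raster.classes is not None:
            out[name] = pd.Categorical(raster.class_at(pts[:, 0], pts[:, 1]),
                                       categories=raster.classes)
        else:
            out[name] = sample_raster_at_points(raster, pts)
    out = out.join(nbr.loc[rows.index])
    if drop_border:
        out = out[~out["border"]]
    return out


# ---------------------------------------------------------------------------
# conditional-inference-style regression trees


def _assoc_pvalue(x: np.ndarray, y: np.ndarray, categorical: bool) -> float:
    """Asymptotic p-value of the node-level association test.

    Continuous x: standardised cross-product statistic (correlation-type),
    normal approximation.  Categorical x: one-way mean-contrast quadratic
    statistic, chi-square approximation with (levels - 1) df.
    """
    n = y.size
    yc = y - y.mean()
    ssy = float(np.sum(yc * yc))
    if ssy == 0.0 or n < 3:
        return 1.0
    if not categorical:
        xc = x - x.mean()
        ssx = float(np.sum(xc * xc))
        if ssx == 0.0:
            return 1.0
        z = float(np.sum(xc * yc)) / np.sqrt(ssx * ssy / (n - 1))
        return float(2.0 * stats.norm.sf(abs(z)))
    codes, counts = np.unique(x, return_counts=True)
    if codes.size < 2:
        return 1.0
    group_means = np.array([y[x == c].mean() for c in codes])
    stat = (n - 1) * float(np.sum(counts * (group_means - y.mean()) ** 2)) / ssy
    return float(stats.chi2.sf(stat, df=codes.size - 1))


def _best_cut_continuous(x, y, min_leaf):
    """Best variance-reduction cutpoint on a continuous predictor."""
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    n = xs.size
    csum = np.cumsum(ys)
    total = csum[-1]
    n_left = np.arange(1, n)
    valid = (xs[:-1] < xs[1:]) & (n_left >= min_leaf) & (n - n_left >= min_leaf)
    if not valid.any():
        return None, -np.inf
    left = csum[:-1]
    # reduction in SS: n_l*mean_l^2 + n_r*mean_r^2 - n*mean^2 (constant offset)
    score = left ** 2 / n_left + (total - left) ** 2 / (n - n_left)
    score = np.where(valid, score, -np.inf)
    best = int(np.argmax(score))
    cut = 0.5 * (xs[best] + xs[best + 1])
    return cut, float(score[best] - total ** 2 / n)


def _best_cut_categorical(x, y, min_leaf, max_exhaustive=8):
    """Best binary level-subset split on a categorical predictor.

    Exhaustive subset search up to ``max_exhaustive`` levels; beyond that,
    levels are ordered by mean response and searched as an ordinal axis.
    """
    levels = pd.unique(x)
    if levels.size < 2:
        return None, -np.inf
    sums = {lv: y[x == lv].sum() for lv in levels}
    cnts = {lv: int(np.sum(x == lv)) for lv in levels}
    n, total = y.size, float(y.sum())
    if levels.size <= max_exhaustive:
        best_subset, best_score = None, -np.inf
        lv_list = list(levels)
        for r in range(1, levels.size):
            for combo in itertools.combinations(lv_list[1:], r):
                # fix the first level on the left side to halve the search
                subset = (lv_list[0],) + combo if r < levels.size - 1 else None
                if subset is None:
                    continue
                nl = sum(cnts[lv] for lv in subset)
                if nl < min_leaf or n - nl < min_leaf:
                    continue
                sl = sum(sums[lv] for lv in subset)
                score = sl ** 2 / nl + (total - sl) ** 2 / (n - nl)
                if score > best_score:
                    best_subset, best_score = frozenset(subset), score
        # also consider first level alone on the left
        nl = cnts[lv_list[0]]
        if nl >= min_leaf and n - nl >= min_leaf:
            sl = sums[lv_list[0]]
            score = sl ** 2 / nl + (total - sl) ** 2 / (n - nl)
            if score > best_score:
                best_subset, best_score = frozenset({lv_list[0]}), score
        if best_subset is None:
            return None, -np.inf
        return best_subset, float(best_score - total ** 2 / n)
    ordered = sorted(levels, key=lambda lv: sums[lv] / cnts[lv])
    best_subset, best_score = None, -np.inf
    nl, sl = 0, 0.0
    for cutpos in range(len(ordered) - 1):
        nl += cnts[ordered[cutpos]]
        sl += sums[ordered[cutpos]]
        if nl < min_leaf or n - nl < min_leaf:
            continue
        score = sl ** 2 / nl + (total - sl) ** 2 / (n - nl)
        if score > best_score:
            best_subset, best_score = frozenset(ordered[:cutpos + 1]), score
    if best_subset is None:
        return None, -np.inf
    return best_subset, float(best_score - total ** 2 / n)


@dataclass
class _Node:
    value: float
    n: int
    predictor: str | None = None
    p_value: float | None = None
    cutpoint: float | None = None  # continuous split: x <= cutpoint goes left
    left_levels: frozenset | None = None  # categorical split membership
    left: "_Node | None" = None
    right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class CITree:
    """A fitted conditional-inference-style regression tree."""

    root: _Node
    predictors: list[str]
    categorical: dict[str, bool]
    alpha: float
    min_node: int

    @property
    def n_splits(self) -> int:
        def count(node):
            return 0 if node.is_leaf else 1 + count(node.left) + count(node.right)
        return count(self.root)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.empty(len(X))
        cols = {p: X[p].to_numpy() for p in self.predictors}
        idx = np.arange(len(X))

        def route(node, rows):
            if node.is_leaf:
                out[rows] = node.value
                return
            xv = cols[node.predictor][rows]
            if node.cutpoint is not None:
                go_left = xv.astype(float) <= node.cutpoint
            else:
                go_left = np.isin(xv, list(node.left_levels))
            route(node.left, rows[go_left])
            route(node.right, rows[~go_left])

        route(self.root, idx)
        return out


def _column_values(X: pd.DataFrame, name: str, categorical: bool) -> np.ndarray:
    col = X[name]
    if categorical:
        return col.to_numpy(object)
    return col.to_numpy(float)


def fit_citree(X: pd.DataFrame, y, alpha: float = 0.05, min_node: int = 20,
               min_leaf: int = 7, max_depth: int | None = None) -> CITree:
    """Fit a conditional-inference-style regression tree.

    At each node, each predictor is tested for association with the
    response (normal/chi-square approximation); p-values are Bonferroni
    corrected across predictors and the node splits on the most
    significant predictor — ties broken toward the lowest column index —
    at its variance-reduction maximising cutpoint.  Splitting stops when
    the smallest corrected p-value exceeds ``alpha``, the node is smaller
    than ``min_node``, or no cut leaves ``min_leaf`` rows per child.

    Categorical predictors (pandas categorical or object dtype) split on
    level subsets; continuous ones on a threshold.  A constant response
    yields a root-only tree.
    """
    y = np.asarray(y, dtype=float)
    if len(X) != y.size:
        raise ConfigurationError("X and y must have equal length")
    if len(X) < 1:
        raise ConfigurationError("cannot fit a tree on zero rows")
    predictors = list(X.columns)
    categorical = {
        p: (isinstance(X[p].dtype, pd.CategoricalDtype) or X[p].dtype == object)
        for p in predictors}
    cols = {p: _column_values(X, p, categorical[p]) for p in predictors}
    m = len(predictors)

    def grow(rows: np.ndarray, depth: int) -> _Node:
        yy = y[rows]
        node = _Node(value=float(yy.mean()), n=rows.size)
        if rows.size < min_node or np.ptp(yy) == 0.0:
            return node
        if max_depth is not None and depth >= max_depth:
            return node
        pvals = np.array([
            _assoc_pvalue(cols[p][rows], yy, categorical[p]) for p in predictors])
        adj = np.minimum(pvals * m, 1.0)
        best = int(np.argmin(adj))  # argmin takes the lowest index on ties
        if adj[best] > alpha:
            return node
        p = predictors[best]
        xv = cols[p][rows]
        if categorical[p]:
            split, gain = _best_cut_categorical(np.asarray(xv, dtype=object), yy, min_leaf)
            if split is None or gain <= 0:
                return node
            go_left = np.isin(xv, list(split))
            node.left_levels = split
        else:
            split, gain = _best_cut_continuous(np.asarray(xv, dtype=float), yy, min_leaf)
            if split is None or gain <= 0:
                return node
            go_left = np.asarray(xv, dtype=float) <= split
            node.cutpoint = float(split)
        node.predictor = p
        node.p_value = float(adj[best])
        node.left = grow(rows[go_left], depth + 1)
        node.right = grow(rows[~go_left], depth + 1)
        return node

    root = grow(np.arange(len(X)), 0)
    return CITree(root, predictors, categorical, alpha, min_node)


# ---------------------------------------------------------------------------
# ensemble permutation importance


@dataclass
class ImportanceResult:
    """Permutation importance scores, response units squared."""

    scores: pd.Series  # predictor -> mean increase in OOB MSE
    per_iteration: pd.DataFrame  # (n_iter, n_predictors)
    n_iterations: int

    @property
    def ranking(self) -> list[str]:
        return list(self.scores.sort_values(ascending=False).index)

    def standard_errors(self) -> pd.Series:
        return self.per_iteration.std(ddof=1) / np.sqrt(self.n_iterations)

    def to_csv(self, path) -> None:
        out = pd.DataFrame({"importance": self.scores,
                            "se": self.standard_errors()})
        out.index.name = "predictor"
        out.to_csv(path, float_format="%.10g")


def ensemble_importance(X: pd.DataFrame, y, n_iter: int = 500,
                        subsample: float = 0.632, alpha: float = 0.05,
                        min_node: int = 20,
                        rng: np.random.Generator | None = None) -> ImportanceResult:
    """Out-of-bag permutation importance over an ensemble of trees.

    Each iteration fits a tree on a random ``subsample`` fraction of rows
    (without replacement) and measures, on the held-out rows, the increase
    in mean squared prediction error when each predictor column is
    permuted.  The overall score is the mean over iterations; per-
    iteration scores are retained.
    """
    if n_iter < 1:
        raise ConfigurationError("n_iter must be >= 1")
    if len(X.columns) < 2:
        raise ConfigurationError("importance needs at least 2 predictors")
    if not (0.0 < subsample < 1.0):
        raise ConfigurationError("subsample fraction must lie in (0, 1)")
    rng = np.random.default_rng(rng)
    y = np.asarray(y, dtype=float)
    n = len(X)
    n_in = max(min_node, int(round(subsample * n)))
    if n_in >= n:
        raise ConfigurationError("subsample leaves no out-of-bag rows")
    predictors = list(X.columns)
    records = np.zeros((n_iter, len(predictors)))
    for it in range(n_iter):
        perm = rng.permutation(n)
        in_rows, oob = perm[:n_in], perm[n_in:]
        tree = fit_citree(X.iloc[in_rows], y[in_rows], alpha=alpha, min_node=min_node)
        X_oob = X.iloc[oob].reset_index(drop=True)
        y_oob = y[oob]
        base = float(np.mean((tree.predict(X_oob) - y_oob) ** 2))
        for k, p in enumerate(predictors):
            Xp = X_oob.copy()
            Xp[p] = Xp[p].to_numpy()[rng.permutation(len(Xp))]
            mse = float(np.mean((tree.predict(Xp) - y_oob) ** 2))
            records[it, k] = mse - base
    per_iter = pd.DataFrame(records, columns=predictors)
    return ImportanceResult(per_iter.mean(), per_iter, n_iter)
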