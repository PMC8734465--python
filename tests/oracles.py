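"""Independent brute-force O(n^2) oracles for the spatial statistics.

These deliberately avoid the package's spatial indexing and pair
machinery: full distance matrices, direct kernel sums.  They exist only
to cross-check the estimators on small instances.
"""

import numpy as np


def _epan(u, h):
    z = u / h
    return np.where(np.abs(z) < 1.0, 0.75 / h * (1.0 - z * z), 0.0)


def pcf_brute(points, window, r_values, h):
    """Translation-corrected kernel pair-correlation, direct double sum."""
    pts = np.asarray(points, float)
    n = len(pts)
    area = window.width * window.height
    dx = pts[:, 0][:, None] - pts[:, 0][None, :]
    dy = pts[:, 1][:, None] - pts[:, 1][None, :]
    d = np.hypot(dx, dy)
    with np.errstate(divide="ignore"):
        w = area / ((window.width - np.abs(dx)) * (window.height - np.abs(dy)))
    off = ~np.eye(n, dtype=bool)
    out = []
    for r in r_values:
        k = _epan(r - d, h)
        sup = (k > 0) & off  # pairs outside kernel support contribute nothing
        s = float(np.sum(k[sup] * w[sup]))
        out.append(s * area / (n * n * 2.0 * np.pi * r))
    return np.asarray(out)


def kmm_brute(points, marks, r_values, h):
    """Mark-correlation: kernel-weighted mean mark product / mu^2."""
    pts = np.asarray(points, float)
    m = np.asarray(marks, float)
    n = len(pts)
    d = np.hypot(pts[:, 0][:, None] - pts[:, 0][None, :],
                 pts[:, 1][:, None] - pts[:, 1][None, :])
    mm = m[:, None] * m[None, :]
    off = ~np.eye(n, dtype=bool)
    mu = m.mean()
    out = []
    for r in r_values:
        k = _epan(r - d, h)
        den = float(np.sum(k[off]))
        if den == 0.0:
            out.append(0.0)
            continue
        out.append(float(np.sum((k * mm)[off])) / den / mu ** 2)
    return np.asarray(out)


def schlather_brute(points1, marks1, points2, marks2, r_values, h, same=False):
    """Schlather's Moran's-I bivariate mark correlation, direct cross sum."""
    p1 = np.asarray(points1, float)
    p2 = np.asarray(points2, float)
    m1 = np.asarray(marks1, float)
    m2 = np.asarray(marks2, float)
    d = np.hypot(p1[:, 0][:, None] - p2[:, 0][None, :],
                 p1[:, 1][:, None] - p2[:, 1][None, :])
    mu1, mu2 = m1.mean(), m2.mean()
    s1, s2 = m1.std(), m2.std()
    prod = (m1 - mu1)[:, None] * (m2 - mu2)[None, :]
    keep = np.ones_like(d, dtype=bool)
    if same:
        np.fill_diagonal(keep, False)
    out = []
    for r in r_values:
        k = _epan(r - d, h) * keep
        den = float(np.sum(k))
        if den == 0.0:
            out.append(0.0)
            continue
        out.append(float(np.sum(k * prod)) / den / (s1 * s2))
    return np.asarray(out)


def neighborhood_brute(points, dbh, radius):
    """All-pairs neighbourhood features: count, mean/CV dbh, mean/CV dist."""
    pts = np.asarray(points, float)
    dbh = np.asarray(dbh, float)
    n = len(pts)
    out = np.full((n, 5), np.nan)
    for i in range(n):
        dists, vals = [], []
        for j in range(n):
            if j == i:
                continue
            d = float(np.hypot(pts[i, 0] - pts[j, 0], pts[i, 1] - pts[j, 1]))
            if d <= radius:
                dists.append(d)
                vals.append(dbh[j])
        cnt = len(dists)
        out[i, 0] = cnt
        if cnt == 0:
            continue
        vals, dists = np.asarray(vals), np.asarray(dists)
        out[i, 1] = vals.mean()
        out[i, 3] = dists.mean()
        if cnt >= 2:
            if vals.mean() > 0:
                out[i, 2] = vals.std(ddof=1) / vals.mean()
            if dists.mean() > 0:
                out[i, 4] = dists.std(ddof=1) / dists.mean()
    return out
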