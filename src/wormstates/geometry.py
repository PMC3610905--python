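"""State-space geometry: weighted PCA and the triangularity test.

Discovered states form a cloud of 7-parameter points, each weighted by the
probability of the state in its track.  Expectations over the cloud are
probability-weighted, principal components come from diagonalizing the
weighted correlation matrix, and the archetype question -- do the states
fill out a triangle whose corners are pure behavioral types? -- is asked
of the first two components with the statistic

    t = area(convex hull) / area(minimal enclosing triangle),

which is 1 for points arranged in a triangle and ~0.605 for a disc.
Significance comes from permuting one component so the same x's and y's
are paired at random.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

logger = logging.getLogger("wormstates")

__all__ = [
    "StateCloud",
    "TriangleTestResult",
    "weighted_pca",
    "convex_hull_area",
    "min_enclosing_triangle",
    "triangularity_test",
]


@dataclass
class StateCloud:
    """Weighted 7-D state points with provenance ids."""

    points: np.ndarray                 # (n, p)
    weights: np.ndarray                # (n,) state probabilities
    ids: list = field(default_factory=list)  # (experiment, track, state index)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, float))
        self.weights = np.asarray(self.weights, float).ravel()
        if self.weights.shape[0] != self.points.shape[0]:
            raise ValueError("weights must match points")
        if np.any((self.weights < 0) | (self.weights > 1)):
            raise ValueError("weights must lie in [0, 1]")

    def filtered(self, min_weight: float) -> "StateCloud":
        """Drop low-probability states (outlier control)."""
        keep = self.weights > min_weight
        ids = [i for i, k in zip(self.ids, keep) if k] if self.ids else []
        return StateCloud(self.points[keep], self.weights[keep], ids)


@dataclass
class TriangleTestResult:
    t_ratio: float
    p_value: float
    n_permutations: int
    hull_vertices: np.ndarray
    triangle: np.ndarray
    null_ratios: np.ndarray | None = None


# ---------------------------------------------------------------------------
# weighted PCA


def weighted_standardize(cloud: StateCloud):
    """Standardize each parameter to weighted mean 0, weighted SD 1."""
    w = cloud.weights / cloud.weights.sum()
    mean = w @ cloud.points
    var = w @ (cloud.points - mean) ** 2
    # constant parameters carry no information: standardized to zero
    dead = var <= 1e-12 * max(float(var.max()), 1.0)
    sd = np.where(dead, 1.0, np.sqrt(var))
    z = (cloud.points - mean) / sd
    z[:, dead] = 0.0
    return z, mean, sd


def weighted_pca(cloud: StateCloud, n_components: int = 2):
    """Probability-weighted PCA of the correlation matrix.

    Weighted expectation is E[x] = sum_i pi_i x_i / sum_i pi_i; duplicating
    a point and doubling its weight are equivalent.  Returns components
    (rows), scores for all points, and variance fractions (sum to 1).
    """
    if cloud.points.shape[0] < 2 or cloud.weights.sum() <= 0:
        raise ValueError("need >= 2 points with positive total weight")
    z, _, _ = weighted_standardize(cloud)
    w = cloud.weights / cloud.weights.sum()
    corr = (z * w[:, None]).T @ z
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    components = evecs[:, :n_components].T
    scores = z @ evecs[:, :n_components]
    fractions = evals / evals.sum()
    return components, scores, fractions


# ---------------------------------------------------------------------------
# hull and minimal enclosing triangle


def convex_hull_area(points_2d: np.ndarray):
    """Shoelace area of the convex hull; vertices in CCW order."""
    pts = np.atleast_2d(np.asarray(points_2d, float))
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    try:
        hull = ConvexHull(pts)
    except Exception as exc:  # qhull rejects degenerate (collinear) input
        logger.warning("degenerate hull (%s); area 0", exc)
        return 0.0, pts[:0]
    return float(hull.volume), pts[hull.vertices]  # .volume is area in 2-D


def _support(verts: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    """Support function h(theta) = max_v (cos, sin) . v over hull vertices."""
    n = np.column_stack([np.cos(thetas), np.sin(thetas)])
    return (n @ verts.T).max(axis=1)


def _triangle_from_lines(thetas: np.ndarray, hs: np.ndarray):
    """Vertices of the triangle bounded by 3 support lines n_i . x = h_i."""
    pts = []
    for i, j in ((0, 1), (1, 2), (2, 0)):
        ni = np.array([np.cos(thetas[i]), np.sin(thetas[i])])
        nj = np.array([np.cos(thetas[j]), np.sin(thetas[j])])
        den = ni[0] * nj[1] - ni[1] * nj[0]
        if abs(den) < 1e-14:
            return None
        x = (hs[i] * nj[1] - hs[j] * ni[1]) / den
        y = (hs[j] * ni[0] - hs[i] * nj[0]) / den
        pts.append((x, y))
    return np.asarray(pts)


def _line_triangle_areas(ta, ha, tb, hb, tc, hc):
    """Areas of triangles bounded by support-line triples (broadcasting).

    Angles are outward normals; a triple bounds a triangle iff each angular
    gap lies in (0, pi).  Infeasible triples get infinite area.
    """
    g1 = tb - ta
    g2 = tc - tb
    g3 = 2 * np.pi - (tc - ta)
    eps = 1e-9
    good = (g1 > eps) & (g1 < np.pi - eps) & (g2 > eps) & \
           (g2 < np.pi - eps) & (g3 > eps) & (g3 < np.pi - eps)

    def inter(t1, h1, t2, h2):
        den = np.sin(t2 - t1)
        den = np.where(np.abs(den) < 1e-15, np.nan, den)
        x = (h1 * np.sin(t2) - h2 * np.sin(t1)) / den
        y = (h2 * np.cos(t1) - h1 * np.cos(t2)) / den
        return x, y

    x1, y1 = inter(ta, ha, tb, hb)
    x2, y2 = inter(tb, hb, tc, hc)
    x3, y3 = inter(tc, hc, ta, ha)
    area = 0.5 * np.abs((x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1))
    return np.where(good & np.isfinite(area), area, np.inf)


def _flush_triple_areas(normals: np.ndarray, verts: np.ndarray):
    """Areas of all triangles whose three sides are flush with hull edges.

    Corner optima of the minimal-triangle problem (two or three flush
    sides) live exactly on this candidate set; returns (best area, angles)
    or (inf, None) if no edge triple bounds a triangle.
    """
    h = normals.size
    # corner optima matter for small, kinky hulls; for large smooth hulls the
    # continuous search is accurate and the O(h^3) enumeration is wasteful
    if h < 3 or h > 60:
        return np.inf, None
    th = np.sort(normals)
    hh = _support(verts, th)
    i, j, k = np.meshgrid(np.arange(h), np.arange(h), np.arange(h),
                          indexing="ij")
    mask = (i < j) & (j < k)
    t1, t2, t3 = th[i[mask]], th[j[mask]], th[k[mask]]
    h1, h2, h3 = hh[i[mask]], hh[j[mask]], hh[k[mask]]
    areas = _line_triangle_areas(t1, h1, t2, h2, t3, h3)
    if not np.isfinite(areas).any():
        return np.inf, None
    b = int(np.argmin(areas))
    return float(areas[b]), np.array([t1[b], t2[b], t3[b]])


def min_enclosing_triangle(points_2d: np.ndarray, n_grid: int = 17,
                           n_zoom: int = 4, n_candidates: int = 24):
    """Minimal-area triangle containing the points.

    The optimum always has one side flush with a hull edge.  The search
    fixes each hull edge's outward normal as one side direction and scans
    the other two side angles on a coarse grid over the hull's support
    function (one vectorized evaluation over all edges), then zoom-refines
    the most promising cells simultaneously.  Corner optima with two or
    three flush sides are additionally evaluated exactly from the hull
    edge normals.
    """
    pts = np.atleast_2d(np.asarray(points_2d, float))
    area_hull, hull_pts = convex_hull_area(pts)
    if area_hull == 0.0:
        raise ValueError("degenerate (collinear) input")
    verts = hull_pts
    h = verts.shape[0]
    edges = verts[(np.arange(h) + 1) % h] - verts
    # outward normal of CCW edge (dx, dy) is (dy, -dx)
    normals = np.arctan2(-edges[:, 0], edges[:, 1])
    E = normals.size

    flush_area, flush_angles = _flush_triple_areas(normals, verts)

    # coarse pass: all flush edges at once
    grid0 = np.linspace(0.0, np.pi, n_grid)
    ta = normals[:, None, None]
    tb = ta + grid0[None, :, None]
    tc = tb + grid0[None, None, :]
    ha = _support(verts, normals)[:, None, None]
    hb = _support(verts, tb.ravel()).reshape(tb.shape)
    hc = _support(verts, tc.ravel()).reshape(tc.shape)
    A0 = _line_triangle_areas(ta, ha, tb, hb, tc, hc)

    order = np.argsort(A0, axis=None)[:n_candidates]
    order = order[np.isfinite(A0.ravel()[order])]
    if order.size == 0 and not np.isfinite(flush_area):
        raise ValueError("minimal triangle search failed")
    ei, bi, ci = np.unravel_index(order, A0.shape)
    thA = normals[ei]
    b0 = grid0[bi]
    c0 = grid0[ci]
    best_area = float(A0.ravel()[order[0]]) if order.size else np.inf
    best_t = (np.array([thA[0], thA[0] + b0[0], thA[0] + b0[0] + c0[0]])
              if order.size else None)

    span = np.pi / (n_grid - 1) * 1.5
    off = np.linspace(-1.0, 1.0, n_grid)
    for _level in range(n_zoom):
        B = b0[:, None, None] + span * off[None, :, None]
        C = c0[:, None, None] + span * off[None, None, :]
        tb = thA[:, None, None] + B
        tc = tb + C
        ha = _support(verts, thA)[:, None, None]
        hb = _support(verts, tb.ravel()).reshape(tb.shape)
        hc = _support(verts, tc.ravel()).reshape(tc.shape)
        A = _line_triangle_areas(thA[:, None, None], ha, tb, hb, tc, hc)
        flat = A.reshape(A.shape[0], -1)
        kmin = np.argmin(flat, axis=1)
        vals = flat[np.arange(flat.shape[0]), kmin]
        i1, j1 = np.unravel_index(kmin, A.shape[1:])
        improved = np.isfinite(vals)
        b0 = np.where(improved, b0 + span * off[i1], b0)
        c0 = np.where(improved, c0 + span * off[j1], c0)
        k = int(np.argmin(vals))
        if np.isfinite(vals[k]) and vals[k] < best_area:
            best_area = float(vals[k])
            best_t = np.array([thA[k], thA[k] + b0[k],
                               thA[k] + b0[k] + c0[k]])
        span *= 1.5 / (n_grid - 1)

    if flush_area < best_area:
        best_area, best_t = flush_area, flush_angles
    if best_t is None:
        raise ValueError("minimal triangle search failed")
    tri = _triangle_from_lines(best_t, _support(verts, best_t))
    return tri, float(best_area)


# ---------------------------------------------------------------------------
# triangularity permutation test


def triangularity_test(
    points_2d: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    keep_null: bool = False,
) -> TriangleTestResult:
    """Permutation test of triangularity of a 2-D point cloud.

    The observed statistic is hull area over minimal-triangle area; the
    null re-pairs the same x's and y's by permuting the second coordinate.
    The p-value uses the add-one estimator (never exactly zero).
    """
    pts = np.atleast_2d(np.asarray(points_2d, float))
    if pts.shape[0] < 4:
        raise ValueError("need at least 4 points")
    area_hull, hull_pts = convex_hull_area(pts)
    tri, area_tri = min_enclosing_triangle(pts)
    t_obs = area_hull / area_tri

    rng = np.random.default_rng(seed)
    count = 0
    null = np.empty(n_perm) if keep_null else None
    y = pts[:, 1].copy()
    for k in range(n_perm):
        perm = np.column_stack([pts[:, 0], rng.permutation(y)])
        try:
            ah, _ = convex_hull_area(perm)
            _, at = min_enclosing_triangle(perm)
            t_k = ah / at
        except ValueError:
            t_k = 0.0
        if t_k >= t_obs:
            count += 1
        if keep_null:
            null[k] = t_k
    p = (1.0 + count) / (1.0 + n_perm)
    return TriangleTestResult(
        t_ratio=float(t_obs), p_value=float(p), n_permutations=n_perm,
        hull_vertices=hull_pts, triangle=tri, null_ratios=null,
    )
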