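"""Behavioral dissimilarity between recordings, metrification and MDS.

If animal A and animal B behave alike, B's fitted model should describe
A's record nearly as well as A's own model.  With L(A|M) the
log-likelihood per valid point (bits) of record A under model M,

    D_model(A, B) = 1/2 [ (L(A|M_A) - L(A|M_B)) + (L(B|M_B) - L(B|M_A)) ].

Raw model likelihood ignores differences in how much time the animals
spend in each state, so a state-probability term is added from the
large-N limit of the multinomial likelihood,

    Lambda(A|B) = sum_i q_i log2(p_i / q_i)   (<= 0, -KL(q||p)),

where q is A's occupancy of B's states and p is B's own occupancy; fit
dissimilarity is the sum of the symmetrized model and probability terms.
State dissimilarity replaces B's fitted transition matrix with the plain
lifetime-parameterized one so that only B's state parameters inform the
cross fit, and uses no probability term.

Dissimilarities are not metric; a distance is derived by adding a
constant c to every edge of the complete graph and taking all-pairs
shortest paths, with c chosen to maximize the reflective correlation
between the graph distances and the raw dissimilarities.  The metrified
distances are embedded by MDS: Torgerson double-centering for the start,
then gradient minimization of a spring potential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.sparse.csgraph import shortest_path

from .hmm import FitResult, HMMModel, forward_backward
from .motion import MotionSeries

logger = logging.getLogger("wormstates")

__all__ = [
    "DissimMatrix",
    "MDSResult",
    "cross_loglik",
    "model_dissimilarity",
    "prob_dissimilarity",
    "fit_dissimilarity",
    "state_dissimilarity",
    "pairwise_dissimilarity",
    "metricize",
    "mds_embed",
    "recovery_trend_test",
]

_LOG2 = np.log(2.0)
_EPS_OCC = 1e-12


@dataclass
class DissimMatrix:
    values: np.ndarray   # (n, n)
    kind: str            # fit | state | model
    ids: list

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("dissimilarity matrix must be symmetric")
        self.values = v


@dataclass
class MDSResult:
    locations: np.ndarray
    stress: float
    c_offset: float = 0.0
    converged: bool = True


# ---------------------------------------------------------------------------
# cross likelihoods and dissimilarities


def cross_loglik(series: MotionSeries, model: HMMModel) -> tuple[float, np.ndarray]:
    """Log-likelihood per valid point (bits) of a series under a model,
    plus the series' occupancy of the model's states."""
    fit = forward_backward(series, model)
    q = fit.posteriors[series.valid].mean(axis=0)
    return fit.loglik_per_point / _LOG2, q


def model_dissimilarity(
    series_a: MotionSeries, model_a: HMMModel,
    series_b: MotionSeries, model_b: HMMModel,
) -> float:
    """Symmetrized self-vs-cross likelihood gap, bits per point."""
    laa, _ = cross_loglik(series_a, model_a)
    lab, _ = cross_loglik(series_a, model_b)
    lbb, _ = cross_loglik(series_b, model_b)
    lba, _ = cross_loglik(series_b, model_a)
    return 0.5 * ((laa - lab) + (lbb - lba))


def _multinomial_limit(q: np.ndarray, p: np.ndarray) -> float:
    """Lambda = sum_i q_i log2(p_i / q_i); 0 iff q == p, else negative."""
    q = np.asarray(q, float)
    p = np.asarray(p, float)
    if abs(q.sum() - 1) > 1e-6 or abs(p.sum() - 1) > 1e-6:
        raise ValueError("occupancies must be probability distributions")
    if np.any((p <= 0) & (q > 0)):
        logger.warning("zero model occupancy with nonzero cross occupancy; "
                       "flooring at %g", _EPS_OCC)
    p = np.maximum(p, _EPS_OCC)
    mask = q > 0
    return float(np.sum(q[mask] * np.log2(p[mask] / q[mask])))


def prob_dissimilarity(q_ab, p_b, q_ba=None, p_a=None) -> float:
    """State-probability dissimilarity in bits per point.

    One-sided (q_ba omitted): -Lambda(A|B).  Two-sided: the symmetrized
    average -1/2 [Lambda(A|B) + Lambda(B|A)].
    """
    lam_ab = _multinomial_limit(q_ab, p_b)
    if q_ba is None:
        return -lam_ab
    lam_ba = _multinomial_limit(q_ba, p_a)
    return -0.5 * (lam_ab + lam_ba)


def fit_dissimilarity(
    series_a: MotionSeries, model_a: HMMModel, fit_a: FitResult,
    series_b: MotionSeries, model_b: HMMModel, fit_b: FitResult,
) -> float:
    """Model dissimilarity plus state-probability dissimilarity (bits/point)."""
    laa, _ = cross_loglik(series_a, model_a)
    lab, q_ab = cross_loglik(series_a, model_b)
    lbb, _ = cross_loglik(series_b, model_b)
    lba, q_ba = cross_loglik(series_b, model_a)
    d_model = 0.5 * ((laa - lab) + (lbb - lba))
    p_a = fit_a.posteriors[series_a.valid].mean(axis=0)
    p_b = fit_b.posteriors[series_b.valid].mean(axis=0)
    d_prob = prob_dissimilarity(q_ab, p_b, q_ba, p_a)
    return d_model + d_prob


def _states_only_model(model: HMMModel) -> HMMModel:
    """The model with its fitted transition matrix replaced by the plain
    lifetime-parameterized one (state parameters are the only information)."""
    return HMMModel(states=model.states, transition=model.transition,
                    nu=model.nu, transition_override=None)


def state_dissimilarity(
    series_a: MotionSeries, model_a: HMMModel,
    series_b: MotionSeries, model_b: HMMModel,
) -> float:
    """Like model dissimilarity, but cross fits use lifetime-form transitions
    with the other animal's state parameters only; no probability term."""
    ma = _states_only_model(model_a)
    mb = _states_only_model(model_b)
    laa, _ = cross_loglik(series_a, ma)
    lab, _ = cross_loglik(series_a, mb)
    lbb, _ = cross_loglik(series_b, mb)
    lba, _ = cross_loglik(series_b, ma)
    return 0.5 * ((laa - lab) + (lbb - lba))


def pairwise_dissimilarity(
    entries: list[tuple[MotionSeries, HMMModel, FitResult]],
    kind: str = "fit",
    ids: list | None = None,
) -> DissimMatrix:
    """All-pairs dissimilarity matrix over fitted tracks."""
    n = len(entries)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sa, ma, fa = entries[i]
            sb, mb, fb = entries[j]
            if kind == "fit":
                d = fit_dissimilarity(sa, ma, fa, sb, mb, fb)
            elif kind == "model":
                d = model_dissimilarity(sa, ma, sb, mb)
            elif kind == "state":
                d = state_dissimilarity(sa, ma, sb, mb)
            else:
                raise ValueError(f"unknown kind: {kind}")
            D[i, j] = D[j, i] = d
    return DissimMatrix(D, kind, ids or list(range(n)))


# ---------------------------------------------------------------------------
# metrification


def _reflective_corr(a: np.ndarray, b: np.ndarray) -> float:
    num = float(np.sum(a * b))
    den = float(np.sqrt(np.sum(a * a) * np.sum(b * b)))
    return num / den if den > 0 else 0.0


def _graph_distance(D: np.ndarray, c: float) -> np.ndarray:
    W = D + c
    np.fill_diagonal(W, 0.0)
    return shortest_path(W, method="FW", directed=False)


def metricize(D: np.ndarray | DissimMatrix):
    """All-pairs shortest-path distances on edge weights D_ij + c.

    c is chosen (bounded scalar search, coarse-grid fallback) to maximize
    the reflective correlation between the graph distances and the raw
    dissimilarities.  The output satisfies the triangle inequality exactly.
    """
    if isinstance(D, DissimMatrix):
        D = D.values
    D = np.asarray(D, float)
    off = ~np.eye(D.shape[0], dtype=bool)
    d_off = D[off]
    c_min = max(0.0, -float(d_off.min()))
    c_max = float(d_off.max()) + c_min + 1e-9

    def neg_rho(c):
        return -_reflective_corr(_graph_distance(D, c)[off], d_off)

    grid = np.linspace(c_min, c_max, 25)
    vals = np.array([neg_rho(c) for c in grid])
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    if hi > lo:
        res = minimize_scalar(neg_rho, bounds=(lo, hi), method="bounded")
        c_star = float(res.x) if res.fun <= vals[k] else float(grid[k])
    else:
        c_star = float(grid[k])
    G = _graph_distance(D, c_star)
    return G, c_star


# ---------------------------------------------------------------------------
# multidimensional scaling


def _torgerson(D: np.ndarray, k: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:k]
    lam = np.maximum(evals[order], 0.0)
    return evecs[:, order] * np.sqrt(lam)


def _stress(X: np.ndarray, D: np.ndarray) -> float:
    iu = np.triu_indices(D.shape[0], 1)
    d = np.linalg.norm(X[iu[0]] - X[iu[1]], axis=1)
    return float(np.sqrt(np.sum((d - D[iu]) ** 2) / np.sum(D[iu] ** 2)))


def mds_embed(
    distances: np.ndarray,
    k: int = 2,
    weights: np.ndarray | None = None,
    init: np.ndarray | None = None,
    seed: int = 0,
    maxiter: int = 2000,
) -> MDSResult:
    """Spring-potential MDS of a distance matrix.

    Minimizes U = sum_{i<j} w_ij (|x_i - x_j| - D_ij)^2 by L-BFGS with an
    analytic gradient, starting from Torgerson double-centering (or the
    supplied configuration, e.g. PCA scores for a state cloud).  Pair
    weights default to 1; for state clouds pass w_ij = pi_i * pi_j via the
    per-point ``weights`` vector.
    """
    D = np.asarray(distances, float)
    n = D.shape[0]
    iu, ju = np.triu_indices(n, 1)
    Dij = D[iu, ju]
    if weights is None:
        Wij = np.ones_like(Dij)
    else:
        wv = np.asarray(weights, float).ravel()
        Wij = wv[iu] * wv[ju]
    X0 = _torgerson(D, k) if init is None else np.asarray(init, float).copy()
    if X0.shape != (n, k):
        raise ValueError("init configuration has wrong shape")
    rng = np.random.default_rng(seed)
    X0 = X0 + 1e-9 * rng.standard_normal(X0.shape)  # break exact ties

    def objgrad(xflat):
        X = xflat.reshape(n, k)
        diff = X[iu] - X[ju]
        d = np.maximum(np.linalg.norm(diff, axis=1), 1e-12)
        resid = d - Dij
        U = float(np.sum(Wij * resid ** 2))
        coef = (2.0 * Wij * resid / d)[:, None]
        G = np.zeros((n, k))
        np.add.at(G, iu, coef * diff)
        np.add.at(G, ju, -coef * diff)
        return U, G.ravel()

    res = minimize(objgrad, X0.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-10})
    X = res.x.reshape(n, k)
    if not res.success:
        logger.warning("MDS optimizer did not fully converge: %s", res.message)
    return MDSResult(locations=X, stress=_stress(X, D), converged=bool(res.success))


# ---------------------------------------------------------------------------
# starvation-recovery trend test


def recovery_trend_test(
    t1: np.ndarray,
    t2: np.ndarray,
    dissim: np.ndarray,
    cut_length_s: float = 900.0,
    exclude_adjacent: bool = True,
    against: str = "interval",
):
    """Slope test of mean dissimilarity against time separation (or time).

    ``against='interval'`` regresses the mean dissimilarity per |t1 - t2|
    on the interval; adjacent cuts (end-to-start gap < one cut length,
    i.e. |t1 - t2| < 2 * cut_length) are excluded when flagged, since a
    persisting state straddling the cut boundary would make contiguous
    cuts artificially similar.  ``against='time'`` regresses on the later
    cut's start time.  Returns (slope, p_value, n_groups).
    """
    t1 = np.asarray(t1, float)
    t2 = np.asarray(t2, float)
    d = np.asarray(dissim, float)
    if against == "interval":
        x = np.abs(t2 - t1)
        keep = x >= 2 * cut_length_s - 1e-9 if exclude_adjacent else x > 0
    elif against == "time":
        x = np.maximum(t1, t2)
        keep = np.ones_like(x, bool)
    else:
        raise ValueError("against must be 'interval' or 'time'")
    x, d = x[keep], d[keep]
    xs = np.unique(x)
    if xs.size < 3:
        raise ValueError("need at least 3 distinct abscissa values")
    means = np.array([d[x == v].mean() for v in xs])
    counts = np.array([(x == v).sum() for v in xs], float)
    # weighted regression: the variance of a group mean scales with 1/count
    w = counts / counts.sum()
    xb = w @ xs
    yb = w @ means
    sxx = w @ ((xs - xb) ** 2)
    slope = w @ ((xs - xb) * (means - yb)) / sxx
    intercept = yb - slope * xb
    resid = means - (intercept + slope * xs)
    dof = xs.size - 2
    sigma2 = (w @ resid ** 2) * xs.size / dof
    se = np.sqrt(sigma2 / (xs.size * sxx))
    from scipy.stats import t as t_dist
    tval = slope / se
    p = 2 * t_dist.sf(abs(tval), dof)
    return float(slope), float(p), int(xs.size)
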