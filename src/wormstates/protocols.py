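"""Fitting protocols: open-loop, closed-loop, unbiased discovery, standards.

An *open-loop* fit decodes a series under fixed states and re-estimates
what the animal actually did while each state was probable.  A
*closed-loop* fit iterates decode and re-estimation to a fixed point,
with two stabilizing constraints: transitions are held at the
lifetime-parameterized form, and the second-moment parameters are pooled
across states (a weighted average), which bounds emission-probability
ratios.  After convergence one relaxation pass re-estimates per-state
variances freely and takes a single Baum-Welch step on the transition
matrix.  An *unbiased* fit seeds the closed loop from the data alone:
the one-state fit is split by cloning the state and nudging the clone's
mean speed upward, the two-state fit is split again, and the fit with the
highest excess entropy (ties to fewer states) is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .hmm import (
    FitResult,
    HMMModel,
    StateDescription,
    TransitionSpec,
    excess_entropy,
    forward_backward,
    reestimate_state,
    reestimate_transitions,
    transition_matrix,
)
from .motion import MotionSeries, scramble_series

logger = logging.getLogger("wormstates")

__all__ = [
    "open_loop_fit",
    "closed_loop_fit",
    "unbiased_fit",
    "UnbiasedFit",
    "build_standard_states",
    "standard_fit",
    "rate_graph",
    "entropy_null",
    "typical_segment",
]

_MIN_STATE_WEIGHT = 2.0  # posterior mass below which a split is abandoned


def _reestimate_all(series, posteriors, m, variance_floor, labels=None):
    labels = labels or [""] * m
    return [
        reestimate_state(series, posteriors, j, variance_floor, labels[j])
        for j in range(m)
    ]


def open_loop_fit(
    series: MotionSeries,
    states: list[StateDescription],
    spec: TransitionSpec,
    nu: int = 5,
    variance_floor: float = 1e-6,
) -> tuple[FitResult, list[StateDescription]]:
    """One decode under fixed states, then one re-estimation per state."""
    model = HMMModel(states=list(states), transition=spec, nu=nu)
    fit = forward_backward(series, model)
    new_states = _reestimate_all(series, fit.posteriors, model.m, variance_floor,
                                 [s.label for s in states])
    return fit, new_states


def _pool_second_moments(states: list[StateDescription], weights: np.ndarray):
    """Replace each state's Sigma by the weight-averaged Sigma.

    Averaging the full second-moment block (variances and covariance)
    keeps it positive definite, since each per-state block is.
    """
    w = np.asarray(weights, float)
    w = w / w.sum()
    var_s = float(w @ [s.var_s for s in states])
    var_a = float(w @ [s.var_a for s in states])
    var_ar = float(w @ [s.var_ar for s in states])
    cov_sa = float(w @ [s.cov_sa for s in states])
    return [
        s.copy(var_s=var_s, var_a=var_a, var_ar=var_ar, cov_sa=cov_sa)
        for s in states
    ]


def closed_loop_fit(
    series: MotionSeries,
    init_states: list[StateDescription],
    spec: TransitionSpec,
    nu: int = 5,
    tol: float = 1e-4,
    max_iter: int = 200,
    variance_floor: float = 1e-6,
    relax: bool = True,
) -> tuple[FitResult, list[StateDescription]]:
    """Iterated fit/re-estimate to a fixed point, then one relaxed pass.

    Raises ``_StateCollapse`` internally (returned as ``None`` states) if a
    state's posterior mass vanishes; callers treat that as a failed split.
    """
    states = list(init_states)
    m = len(states)
    model = HMMModel(states=states, transition=spec, nu=nu)
    converged = False
    fit = None
    for it in range(max_iter):
        fit = forward_backward(series, model)
        weights = fit.posteriors[series.valid].sum(axis=0)
        if m > 1 and weights.min() < _MIN_STATE_WEIGHT:
            logger.debug("state collapsed at iteration %d (weights %s)", it, weights)
            return None, None
        new_states = _reestimate_all(series, fit.posteriors, m, variance_floor,
                                     [s.label for s in states])
        new_states = _pool_second_moments(new_states, weights)
        delta = max(
            float(np.max(np.abs(a.as_vector() - b.as_vector())))
            for a, b in zip(new_states, states)
        )
        states = new_states
        model = HMMModel(states=states, transition=spec, nu=nu)
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("closed-loop fit did not converge in %d iterations", max_iter)

    if relax:
        # relaxation: free per-state variances + one Baum-Welch transition step
        fit = forward_backward(series, model)
        states = _reestimate_all(series, fit.posteriors, m, variance_floor,
                                 [s.label for s in states])
        T_prior = transition_matrix(spec)
        T_new = reestimate_transitions(fit.expected_transitions, fallback=T_prior)
        model = HMMModel(states=states, transition=spec, nu=nu,
                         transition_override=T_new)
        fit = forward_backward(series, model)
    fit.converged = converged
    return fit, states


@dataclass
class UnbiasedFit:
    """All fits tried by unbiased state discovery plus the selected one."""

    fits: dict = field(default_factory=dict)       # m -> FitResult
    states: dict = field(default_factory=dict)     # m -> list[StateDescription]
    best_m: int = 1
    loglik_gains: dict = field(default_factory=dict)  # m -> per-point gain vs m-1

    @property
    def best(self) -> FitResult:
        return self.fits[self.best_m]

    @property
    def best_states(self) -> list:
        return self.states[self.best_m]

    @property
    def top_state_index(self) -> int:
        return int(np.argmax([s.pi for s in self.best_states]))


def _split_fastest(states: list[StateDescription], split_eps: float):
    """Clone the highest-mean-speed state, nudging the clone's mu_s up."""
    j = int(np.argmax([s.mu_s for s in states]))
    clone = states[j].copy(mu_s=states[j].mu_s + split_eps)
    half = states[j].pi / 2.0
    out = [s.copy() for s in states]
    out[j] = out[j].copy(pi=half)
    out.append(clone.copy(pi=half))
    return out


def unbiased_fit(
    series: MotionSeries,
    spec_tau: float,
    dt: float,
    nu: int = 5,
    split_eps: float = 0.1,
    tol: float = 1e-4,
    max_iter: int = 200,
    variance_floor: float = 1e-6,
    max_states: int = 3,
) -> UnbiasedFit:
    """State discovery seeded from the data alone, selected by excess entropy."""
    if series.n_valid < 3:
        raise ValueError("series too short for unbiased fitting")
    result = UnbiasedFit()

    # one-state fit: posterior is identically 1, so it is just global moments
    spec1 = TransitionSpec(tau=spec_tau, dt=dt, m=1)
    model1 = HMMModel(
        states=[reestimate_state(series, np.ones((len(series), 1)), 0,
                                 variance_floor)],
        transition=spec1, nu=nu,
    )
    fit1 = forward_backward(series, model1)
    result.fits[1] = fit1
    result.states[1] = model1.states
    prev_fit, prev_states = fit1, model1.states

    for m in range(2, max_states + 1):
        init = _split_fastest(prev_states, split_eps)
        spec = TransitionSpec(tau=spec_tau, dt=dt, m=m)
        fit, states = closed_loop_fit(
            series, init, spec, nu=nu, tol=tol, max_iter=max_iter,
            variance_floor=variance_floor,
        )
        if fit is None:
            logger.info("%d-state split abandoned (state collapse)", m)
            break
        result.fits[m] = fit
        result.states[m] = states
        result.loglik_gains[m] = fit.loglik_per_point - prev_fit.loglik_per_point
        prev_fit, prev_states = fit, states

    # highest excess entropy wins; ties go to fewer states
    best_m, best_ee = 1, result.fits[1].excess_entropy_bits
    for m in sorted(result.fits):
        ee = result.fits[m].excess_entropy_bits
        if ee > best_ee + 1e-12:
            best_m, best_ee = m, ee
    result.best_m = best_m
    logger.debug("unbiased fit selected m=%d (excess entropy %.3f bits)",
                 best_m, best_ee)
    return result


# ---------------------------------------------------------------------------
# standard (pure-play) states


def build_standard_states(
    groups: dict[str, list[tuple[MotionSeries, UnbiasedFit]]],
    variance_floor: float = 1e-6,
) -> dict[str, StateDescription]:
    """Pool each condition's per-track top states into one standard state.

    For every track in a condition, the most probable state of its unbiased
    fit contributes its posterior-weighted frames.  Means of the pooled
    state are the weight-averaged per-track means; second moments are taken
    about the common pooled means, so they pick up the between-track
    component and are never smaller than the average within-track moments.
    """
    out = {}
    for cond, tracks in groups.items():
        if not tracks:
            raise ValueError(f"condition {cond!r} has no tracks")
        g_all, s_all, a_all, ar_all, r_all = [], [], [], [], []
        for series, ufit in tracks:
            j = ufit.top_state_index
            vi = series.valid
            g_all.append(ufit.best.posteriors[vi, j])
            s_all.append(series.s_hat[vi])
            a_all.append(series.a_hat[vi])
            ar_all.append(series.ar_hat[vi])
            r_all.append(series.r[vi])
        g = np.concatenate(g_all)
        s_hat = np.concatenate(s_all)
        a_hat = np.concatenate(a_all)
        ar_hat = np.concatenate(ar_all)
        r = np.concatenate(r_all)
        N = g.sum()
        p_rev = float(g @ r / N)
        mu_s = float(g @ s_hat / N)
        mu_a = float(g @ a_hat / N)
        bias = N / (N - 1.0)
        ds, da = s_hat - mu_s, a_hat - mu_a
        var_s = max(float(g @ (ds * ds) / N * bias), variance_floor)
        var_a = max(float(g @ (da * da) / N * bias), variance_floor)
        cov_sa = float(g @ (ds * da) / N * bias)
        var_ar = max(float(g @ (ar_hat * ar_hat) / N), variance_floor)
        bound = 0.999 * np.sqrt(var_s * var_a)
        cov_sa = float(np.clip(cov_sa, -bound, bound))
        out[cond] = StateDescription(
            p_rev=p_rev, mu_s=mu_s, mu_a=mu_a, var_s=var_s, var_a=var_a,
            var_ar=var_ar, cov_sa=cov_sa, pi=1.0, label=cond,
        )
    return out


def standard_fit(
    series: MotionSeries,
    standard_states: list[StateDescription],
    spec: TransitionSpec,
    nu: int = 5,
) -> FitResult:
    """Single decode under the fixed standard state descriptions."""
    model = HMMModel(states=list(standard_states), transition=spec, nu=nu)
    return forward_backward(series, model)


def rate_graph(fit: FitResult, dt: float):
    """Occupancies and pairwise switch rates of a fit.

    Rate i->j is the expected number of i->j transitions per unit time
    spent in state i; undefined (NaN) for unoccupied states.
    """
    occ = fit.occupancy
    time_in = fit.posteriors.sum(axis=0) * dt
    m = occ.size
    rates = np.full((m, m), np.nan)
    for i in range(m):
        if time_in[i] > 0:
            rates[i] = fit.expected_transitions[i] / time_in[i]
        rates[i, i] = np.nan
    return occ, rates


def entropy_null(
    series: MotionSeries,
    fit_fn,
    n_scrambles: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Excess entropies of ``fit_fn`` applied to scrambled copies of a series.

    ``fit_fn`` maps a series to an object exposing ``excess_entropy_bits``
    (a FitResult) or to an UnbiasedFit (its selected fit is used).
    """
    if n_scrambles < 1:
        raise ValueError("need at least one scramble")
    rng = np.random.default_rng(seed)
    out = np.empty(n_scrambles)
    for k in range(n_scrambles):
        scr = scramble_series(series, int(rng.integers(2 ** 31)))
        res = fit_fn(scr)
        if isinstance(res, UnbiasedFit):
            res = res.best
        out[k] = res.excess_entropy_bits
    return out


# ---------------------------------------------------------------------------
# statistically typical segments


def typical_segment(
    track_fits: list[tuple[str, MotionSeries, UnbiasedFit]],
    duration_s: float = 90.0,
    p_threshold: float = 0.99,
):
    """Pick the most typical track/state and its central high-confidence window.

    Top-state descriptions are standardized to unit standard deviation
    across tracks; the track whose top state is closest to the pooled
    (weight-averaged) mean wins, ties to the lowest track index.  Returns
    ``(track_id, (t_start, t_end))`` -- the central ``duration_s`` of the
    longest run in which the top state's posterior stays at or above
    ``p_threshold``.
    """
    if not track_fits:
        raise ValueError("no tracks given")
    vecs, weights = [], []
    for _tid, series, ufit in track_fits:
        st = ufit.best_states[ufit.top_state_index]
        vecs.append(st.as_vector())
        weights.append(ufit.best.posteriors[series.valid,
                                            ufit.top_state_index].sum())
    V = np.vstack(vecs)
    w = np.asarray(weights)
    mean = w @ V / w.sum()
    sd = np.sqrt(np.maximum(V.var(axis=0), 1e-12)) if len(V) > 1 else np.ones(V.shape[1])
    z = (V - mean) / sd
    dist = np.linalg.norm(z, axis=1)
    k = int(np.argmin(dist))  # argmin takes the first (lowest index) on ties
    tid, series, ufit = track_fits[k]

    post = ufit.best.posteriors[:, ufit.top_state_index]
    above = post >= p_threshold
    # longest run of consecutive True
    best_len, best_start, run_start = 0, 0, None
    for i, flag in enumerate(np.append(above, False)):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    t = series.times
    t0, t1 = t[best_start], t[best_start + best_len - 1]
    if t1 - t0 < duration_s:
        logger.warning(
            "no run of %.0f s at p >= %.2f; returning longest (%.0f s)",
            duration_s, p_threshold, t1 - t0,
        )
        return tid, (float(t0), float(t1))
    mid = (t0 + t1) / 2.0
    return tid, (float(mid - duration_s / 2.0), float(mid + duration_s / 2.0))
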