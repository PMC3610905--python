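"""Hidden Markov machinery: states, fat-tailed emissions, fitting primitives.

A behavioral state is described by seven parameters: the reversal
probability ``p_rev``, the means of deskewed speed and deskewed
acceleration magnitude, the variances of deskewed speed, acceleration
magnitude and radial acceleration, and the speed/acceleration covariance.
The mean of radial acceleration is fixed at zero (dorsal/ventral
orientation is unknown and assumed random).

Emissions are the product of a Bernoulli term for the reversal bit and a
three-dimensional Student's-t style density over the deskewed continuous
vector ``(s_hat, a_hat, ar_hat)``:

    f(x) = C * (1 + d^2 / nu)^(-(nu + 1) / 2),
    d^2  = (x - mu)^T Sigma^{-1} (x - mu),
    C    = Gamma((nu+1)/2) / (Gamma((nu-2)/2) (nu pi)^{3/2} |Sigma|^{1/2}).

With ``nu = 5`` (the smallest integer for which this three-dimensional
density has a finite mean and variance) the likelihood ratio between two
unit-scale states one standard deviation apart never exceeds 3.79, so a
single outlier frame cannot force a state switch -- the failure mode that
makes Gaussian emissions unusable on this kind of data.

Transitions are parameterized by a single lifetime ``tau``:
``T_ii = exp(-dt/tau)`` and the off-diagonal mass is split evenly among
the other states.  ``tau`` acts as the weight of behavioral evidence
required to recognize a switch rather than as a constraint on observed
lifetimes.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, xlogy

from .motion import MotionSeries

logger = logging.getLogger("wormstates")

__all__ = [
    "StateDescription",
    "TransitionSpec",
    "HMMModel",
    "FitResult",
    "transition_matrix",
    "emission_log_density",
    "likelihood_ratio",
    "forward_backward",
    "reestimate_state",
    "reestimate_transitions",
    "excess_entropy",
]

_PREV_FLOOR = 1e-12  # keeps Bernoulli log terms finite at p_rev in {0, 1}

PARAM_NAMES = ("p_rev", "mu_s", "mu_a", "var_s", "var_a", "var_ar", "cov_sa")


@dataclass
class StateDescription:
    """Seven-parameter description of one behavioral state."""

    p_rev: float
    mu_s: float
    mu_a: float
    var_s: float
    var_a: float
    var_ar: float
    cov_sa: float = 0.0
    pi: float = 1.0          # probability of the state in its track as a whole
    label: str = ""
    vanishing: bool = False  # flagged when the state's posterior weight collapses

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_rev <= 1.0):
            raise ValueError("p_rev must lie in [0, 1]")
        if min(self.var_s, self.var_a, self.var_ar) <= 0:
            raise ValueError("variances must be positive")
        if self.cov_sa ** 2 >= self.var_s * self.var_a:
            raise ValueError("covariance matrix is not positive definite")

    @property
    def mean(self) -> np.ndarray:
        return np.array([self.mu_s, self.mu_a, 0.0])

    @property
    def cov(self) -> np.ndarray:
        return np.array(
            [
                [self.var_s, self.cov_sa, 0.0],
                [self.cov_sa, self.var_a, 0.0],
                [0.0, 0.0, self.var_ar],
            ]
        )

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES])

    @classmethod
    def from_vector(cls, v, **kw) -> "StateDescription":
        return cls(**dict(zip(PARAM_NAMES, np.asarray(v, float))), **kw)

    def copy(self, **changes) -> "StateDescription":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class TransitionSpec:
    """Lifetime-parameterized transition structure."""

    tau: float     # s, mean state lifetime
    dt: float      # s
    m: int         # number of states

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.dt <= 0 or self.m < 1:
            raise ValueError("require tau > 0, dt > 0, m >= 1")


@dataclass
class HMMModel:
    """States plus transition structure; ``transition_override`` holds a
    Baum-Welch re-estimated matrix when one is in use."""

    states: list
    transition: TransitionSpec
    nu: int = 5
    transition_override: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.states) != self.transition.m:
            raise ValueError("state count must match transition spec")
        if self.nu < 5:
            raise ValueError(
                "nu must be >= 5 for a finite mean and variance in 3 dimensions"
            )

    @property
    def m(self) -> int:
        return len(self.states)

    def T(self) -> np.ndarray:
        if self.transition_override is not None:
            return self.transition_override
        return transition_matrix(self.transition)


@dataclass
class FitResult:
    """Posterior decode of one series under one model."""

    posteriors: np.ndarray           # (N, m)
    loglik: float                    # total, nats
    loglik_per_point: float          # nats per valid frame
    expected_transitions: np.ndarray  # (m, m)
    excess_entropy_bits: float
    model: HMMModel
    n_valid: int
    converged: bool = True

    @property
    def occupancy(self) -> np.ndarray:
        """Mean posterior probability of each state."""
        return self.posteriors.mean(axis=0)

    @property
    def argmax_states(self) -> np.ndarray:
        return self.posteriors.argmax(axis=1)


# ---------------------------------------------------------------------------
# transitions


def transition_matrix(spec: TransitionSpec) -> np.ndarray:
    """Row-stochastic lifetime-parameterized transition matrix."""
    m = spec.m
    if m == 1:
        return np.ones((1, 1))
    stay = np.exp(-spec.dt / spec.tau)
    switch = (1.0 - stay) / (m - 1)
    T = np.full((m, m), switch)
    np.fill_diagonal(T, stay)
    return T


# ---------------------------------------------------------------------------
# emissions


def _log_norm_const(nu: int, cov: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ValueError("state covariance matrix is not positive definite")
    return float(
        gammaln((nu + 1) / 2.0)
        - gammaln((nu - 2) / 2.0)
        - 1.5 * np.log(nu * np.pi)
        - 0.5 * logdet
    )


def emission_log_density(
    obs: np.ndarray, r: np.ndarray, state: StateDescription, nu: int = 5
) -> np.ndarray:
    """Log emission density of observation rows under one state.

    ``obs`` is (N, 3) deskewed ``(s_hat, a_hat, ar_hat)``; ``r`` is the
    (N,) reversal bit.  Returns (N,) log densities in nats, normalization
    constant included so that values are comparable across states.
    """
    obs = np.atleast_2d(np.asarray(obs, float))
    r = np.asarray(r, float).ravel()
    cov = state.cov
    logC = _log_norm_const(nu, cov)
    diff = obs - state.mean
    sol = np.linalg.solve(cov, diff.T).T
    d2 = np.einsum("ij,ij->i", diff, sol)
    log_kernel = -(nu + 1) / 2.0 * np.log1p(d2 / nu)
    p = min(max(state.p_rev, _PREV_FLOOR), 1.0 - _PREV_FLOOR)
    log_bern = r * np.log(p) + (1.0 - r) * np.log1p(-p)
    return logC + log_kernel + log_bern


def likelihood_ratio(
    x: float, mu1: float, mu2: float, family: str = "student_t", nu: int = 5
) -> float:
    """1-D diagnostic ratio f(x - mu2) / f(x - mu1) at unit scale.

    With ``family='normal'`` the ratio grows without bound in ``x``; with
    the Student's-t kernel it is bounded (3.79 at nu = 5 for means one
    unit apart), which is why the fat-tailed emission is used.
    """
    z1, z2 = x - mu1, x - mu2
    if family == "normal":
        return float(np.exp((z1 ** 2 - z2 ** 2) / 2.0))
    if family == "student_t":
        return float(
            ((1.0 + z1 ** 2 / nu) / (1.0 + z2 ** 2 / nu)) ** ((nu + 1) / 2.0)
        )
    raise ValueError(f"unknown family: {family}")


def _emission_matrix(series: MotionSeries, model: HMMModel) -> np.ndarray:
    """(N, m) log emission matrix; invalid frames get 0 (no emission term)."""
    n = len(series)
    logE = np.zeros((n, model.m))
    vi = series.valid
    obs = series.observations()[vi]
    r = series.r[vi]
    for j, st in enumerate(model.states):
        logE[vi, j] = emission_log_density(obs, r, st, model.nu)
    return logE


# ---------------------------------------------------------------------------
# forward-backward


def forward_backward(series: MotionSeries, model: HMMModel) -> FitResult:
    """Scaled forward-backward decode of ``series`` under ``model``.

    Invalid timepoints contribute transition factors only, so posteriors
    are interpolated across gaps.  Returns posteriors, the total data
    log-likelihood, expected transition counts and the excess entropy of
    the posterior decode.
    """
    n_valid = series.n_valid
    if n_valid == 0:
        raise ValueError("series has no valid frames")
    logE = _emission_matrix(series, model)
    n, m = logE.shape
    T = model.T()
    # per-row shift keeps emissions in range; total shift added back at the end
    shift = logE.max(axis=1)
    E = np.exp(logE - shift[:, None])

    alpha = np.empty((n, m))
    c = np.empty(n)
    init = np.full(m, 1.0 / m)
    a = init * E[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, n):
        a = (alpha[t - 1] @ T) * E[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]

    beta = np.empty((n, m))
    beta[-1] = 1.0
    xi = np.zeros((m, m))
    for t in range(n - 2, -1, -1):
        be = beta[t + 1] * E[t + 1]
        xi += np.outer(alpha[t], be) * T / c[t + 1]
        beta[t] = (T @ be) / c[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    loglik = float(np.log(c).sum() + shift.sum())
    ee = excess_entropy(gamma)
    return FitResult(
        posteriors=gamma,
        loglik=loglik,
        loglik_per_point=loglik / n_valid,
        expected_transitions=xi,
        excess_entropy_bits=ee,
        model=model,
        n_valid=n_valid,
    )


# ---------------------------------------------------------------------------
# re-estimation


def reestimate_state(
    series: MotionSeries,
    posteriors: np.ndarray,
    state_index: int,
    variance_floor: float = 1e-6,
    label: str = "",
) -> StateDescription:
    """Posterior-weighted moment re-estimate of one state.

    Means are posterior-weighted averages; variances and the covariance
    carry the ``N_i / (N_i - 1)`` correction for plug-in means, except the
    radial-acceleration variance, whose mean is fixed at zero and which is
    therefore the uncorrected weighted mean square.
    """
    vi = series.valid
    g = np.asarray(posteriors, float)[vi, state_index]
    N = g.sum()
    vanishing = N <= 1.0
    if N <= 0:
        raise ValueError("state has zero posterior weight")
    s_hat = series.s_hat[vi]
    a_hat = series.a_hat[vi]
    ar_hat = series.ar_hat[vi]
    r = series.r[vi]

    p_rev = float(g @ r / N)
    mu_s = float(g @ s_hat / N)
    mu_a = float(g @ a_hat / N)
    bias = N / (N - 1.0) if N > 1.0 else 1.0
    ds, da = s_hat - mu_s, a_hat - mu_a
    var_s = float(g @ (ds * ds) / N * bias)
    var_a = float(g @ (da * da) / N * bias)
    cov_sa = float(g @ (ds * da) / N * bias)
    var_ar = float(g @ (ar_hat * ar_hat) / N)  # mean fixed at zero: no correction

    var_s = max(var_s, variance_floor)
    var_a = max(var_a, variance_floor)
    var_ar = max(var_ar, variance_floor)
    # keep the 2x2 speed/acceleration block positive definite
    bound = 0.999 * np.sqrt(var_s * var_a)
    cov_sa = float(np.clip(cov_sa, -bound, bound))

    pi = float(np.mean(np.asarray(posteriors, float)[vi, state_index]))
    return StateDescription(
        p_rev=p_rev, mu_s=mu_s, mu_a=mu_a, var_s=var_s, var_a=var_a,
        var_ar=var_ar, cov_sa=cov_sa, pi=pi, label=label, vanishing=vanishing,
    )


def reestimate_transitions(
    expected: np.ndarray, fallback: np.ndarray | None = None
) -> np.ndarray:
    """Row-normalized expected transition counts (one Baum-Welch step).

    Rows with no expected mass fall back to the corresponding row of
    ``fallback`` (the lifetime-parameterized prior) when given.
    """
    expected = np.asarray(expected, float)
    if np.any(expected < 0):
        raise ValueError("expected transition counts must be nonnegative")
    sums = expected.sum(axis=1, keepdims=True)
    T = np.divide(expected, sums, out=np.zeros_like(expected), where=sums > 0)
    empty = sums.ravel() == 0
    if np.any(empty):
        if fallback is None:
            raise ValueError("empty transition row and no fallback given")
        T[empty] = fallback[empty]
    return T


# ---------------------------------------------------------------------------
# excess entropy


def _entropy_bits(p: np.ndarray, axis=None) -> np.ndarray:
    return -xlogy(p, p).sum(axis=axis) / np.log(2.0)


def excess_entropy(posteriors: np.ndarray) -> float:
    """Occupancy entropy minus mean pointwise entropy, in bits per point.

    Nonnegative by Jensen's inequality and at most log2(m); zero exactly
    when the posteriors are constant in time, maximal for hard labels with
    equal overall occupancy.  Measures how much time-resolved state
    structure a fit extracts beyond the overall state frequencies.
    """
    p = np.atleast_2d(np.asarray(posteriors, float))
    pbar = p.mean(axis=0)
    return float(_entropy_bits(pbar) - _entropy_bits(p, axis=1).mean())
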