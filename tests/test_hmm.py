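"""HMM primitives: transitions, fat-tailed emissions, decoding, entropy."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

import wormstates as ws
from wormstates.hmm import _emission_matrix, emission_log_density

from conftest import random_series


# ---------------------------------------------------------------------------
# transitions


def test_transition_matrix_single_state():
    assert np.array_equal(
        ws.transition_matrix(ws.TransitionSpec(tau=10, dt=1, m=1)), [[1.0]]
    )


def test_one_day_lifetime_gives_86400_fold_switching_penalty():
    T = ws.transition_matrix(ws.TransitionSpec(tau=86400.0, dt=1.0, m=2))
    ratio = T[0, 0] / T[0, 1]
    assert ratio == pytest.approx(86400.0, rel=1e-4)
    assert np.allclose(T.sum(axis=1), 1.0)


def test_five_minute_lifetime_three_states_off_diagonal():
    T = ws.transition_matrix(ws.TransitionSpec(tau=300.0, dt=1.0, m=3))
    expect = (1 - np.exp(-1 / 300.0)) / 2
    assert T[0, 1] == pytest.approx(expect, rel=1e-12)
    assert expect == pytest.approx(1.664e-3, rel=1e-3)


# ---------------------------------------------------------------------------
# emissions


def test_likelihood_ratio_tables():
    # Gaussian kernel: ratios explode with distance from the means
    assert ws.likelihood_ratio(2, 1, 2, "normal") == pytest.approx(1.65, abs=0.005)
    assert ws.likelihood_ratio(5, 1, 2, "normal") == pytest.approx(33.1, abs=0.05)
    # Student's-t kernel (nu=5): ratios stay bounded and fall again
    for x, expect in [(2, 1.73), (5, 3.38), (10, 1.94), (20, 1.38)]:
        assert ws.likelihood_ratio(x, 1, 2, "student_t") == pytest.approx(
            expect, abs=0.005
        )
    assert ws.likelihood_ratio(5, 1, 2, "student_t") == pytest.approx(
        (21 / 14) ** 3, rel=1e-12
    )


def test_t_ratio_maximum_is_bounded():
    xs = np.linspace(-20, 40, 200_001)
    ratios = [ws.likelihood_ratio(x, 1, 2, "student_t") for x in (3.7913,)]
    vals = ((1 + (xs - 1) ** 2 / 5) / (1 + (xs - 2) ** 2 / 5)) ** 3
    x_star = (3 + np.sqrt(21)) / 2
    expect = ((11 + np.sqrt(21)) / 10) ** 3  # exact closed form at x_star
    assert vals.max() == pytest.approx(expect, rel=1e-8)
    assert xs[vals.argmax()] == pytest.approx(x_star, abs=1e-3)
    assert ratios[0] == pytest.approx(expect, abs=1e-4)
    assert vals.max() < 3.79


@pytest.mark.parametrize("state", [
    ws.StateDescription(p_rev=0.3, mu_s=1.0, mu_a=0.5, var_s=0.8, var_a=0.5,
                        var_ar=0.3, cov_sa=0.2),
    ws.StateDescription(p_rev=0.0, mu_s=2.5, mu_a=1.2, var_s=0.1, var_a=2.0,
                        var_ar=0.05, cov_sa=-0.3),
])
def test_emission_density_is_normalized(state):
    # tensor quadrature with x = mu + tan(theta) substitution per axis, which
    # maps the infinite domain to a box and handles the power-law tails
    nodes, w = np.polynomial.legendre.leggauss(120)
    half = np.pi / 2 - 1e-9
    theta = nodes * half
    wt = w * half
    y = np.tan(theta)
    jac = 1.0 / np.cos(theta) ** 2
    X, Y, Z = np.meshgrid(y + state.mu_s, y + state.mu_a, y, indexing="ij")
    obs = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    dens = np.exp(emission_log_density(obs, np.zeros(obs.shape[0]), state))
    dens = dens.reshape(X.shape)
    wj = wt * jac
    val = np.einsum("ijk,i,j,k->", dens, wj, wj, wj)
    assert val / (1 - state.p_rev) == pytest.approx(1.0, abs=1e-3)


def test_emission_mode_and_tails():
    st = ws.StateDescription(p_rev=0.5, mu_s=1.0, mu_a=0.8, var_s=0.5,
                             var_a=0.5, var_ar=0.5)
    at_mode = emission_log_density(st.mean[None, :], np.array([0]), st)[0]
    rng = np.random.default_rng(0)
    other = emission_log_density(rng.normal(1, 2, (100, 3)),
                                 np.zeros(100), st)
    assert np.all(at_mode >= other)
    # heavier tails than a Gaussian of the same scale: t/normal ratio grows
    far = np.array([[30.0, 0.8, 0.0]])
    log_t = emission_log_density(far, np.array([0]), st)[0]
    diff = (far[0] - st.mean)
    d2 = diff @ np.linalg.solve(st.cov, diff)
    log_n = -0.5 * d2  # Gaussian kernel, same Mahalanobis distance
    assert log_t - at_mode > log_n


def test_non_positive_definite_covariance_rejected():
    with pytest.raises(ValueError):
        ws.StateDescription(p_rev=0.1, mu_s=0, mu_a=0, var_s=1.0, var_a=1.0,
                            var_ar=1.0, cov_sa=1.5)


# ---------------------------------------------------------------------------
# forward-backward


def _brute_force(series, model):
    logE = _emission_matrix(series, model)
    T = model.T()
    n, m = logE.shape
    logT = np.log(T)
    paths = list(itertools.product(range(m), repeat=n))
    lps = np.empty(len(paths))
    for k, path in enumerate(paths):
        lp = np.log(1.0 / m) + logE[0, path[0]]
        for t in range(1, n):
            lp += logT[path[t - 1], path[t]] + logE[t, path[t]]
        lps[k] = lp
    logZ = logsumexp(lps)
    w = np.exp(lps - logZ)
    post = np.zeros((n, m))
    xi = np.zeros((m, m))
    for path, p in zip(paths, w):
        for t in range(n):
            post[t, path[t]] += p
        for t in range(n - 1):
            xi[path[t], path[t + 1]] += p
    return logZ, post, xi


@pytest.mark.parametrize("n,m,trial_seed", [(4, 2, 0), (6, 3, 1), (5, 3, 2)])
def test_forward_backward_equals_path_enumeration(n, m, trial_seed):
    rng = np.random.default_rng(trial_seed)
    for rep in range(20):
        states = []
        for j in range(m):
            states.append(ws.StateDescription(
                p_rev=rng.uniform(0.05, 0.95), mu_s=rng.normal(1, 1),
                mu_a=rng.normal(1, 1), var_s=rng.uniform(0.2, 2),
                var_a=rng.uniform(0.2, 2), var_ar=rng.uniform(0.2, 2),
            ))
        model = ws.HMMModel(
            states=states,
            transition=ws.TransitionSpec(tau=rng.uniform(2, 50), dt=1.0, m=m),
        )
        series = random_series(n, seed=100 * trial_seed + rep)
        fit = ws.forward_backward(series, model)
        logZ, post, xi = _brute_force(series, model)
        assert fit.loglik == pytest.approx(logZ, rel=1e-9, abs=1e-9)
        assert np.allclose(fit.posteriors, post, atol=1e-9)
        assert np.allclose(fit.expected_transitions, xi, atol=1e-9)


def test_forward_backward_single_state_and_row_sums():
    series = random_series(50, seed=9)
    st = ws.StateDescription(0.3, 1.0, 1.0, 1.0, 1.0, 1.0)
    model = ws.HMMModel([st], ws.TransitionSpec(tau=100, dt=1, m=1))
    fit = ws.forward_backward(series, model)
    assert np.allclose(fit.posteriors, 1.0)
    direct = emission_log_density(series.observations(), series.r, st).sum()
    assert fit.loglik == pytest.approx(direct, rel=1e-12)
    # row sums on a multi-state decode
    sts = [st, ws.StateDescription(0.1, 3.0, 1.0, 1.0, 1.0, 1.0)]
    fit2 = ws.forward_backward(
        series, ws.HMMModel(sts, ws.TransitionSpec(tau=30, dt=1, m=2))
    )
    assert np.allclose(fit2.posteriors.sum(axis=1), 1.0, atol=1e-9)


def test_loglik_agrees_with_pure_logspace_forward(two_state_pair):
    """Scaled-probability and log-space recursions must agree."""
    states, _seq, series = two_state_pair
    model = ws.HMMModel(states, ws.TransitionSpec(tau=80, dt=1, m=2))
    fit = ws.forward_backward(series, model)
    logE = _emission_matrix(series, model)
    logT = np.log(model.T())
    la = np.log(1 / 2) + logE[0]
    for t in range(1, len(series)):
        la = logsumexp(la[:, None] + logT, axis=0) + logE[t]
    assert fit.loglik == pytest.approx(logsumexp(la), rel=1e-9)


def test_no_underflow_on_long_series(two_state_pair):
    states, _seq, series = two_state_pair
    model = ws.HMMModel(states, ws.TransitionSpec(tau=86400.0, dt=1, m=2))
    fit = ws.forward_backward(series, model)
    assert np.isfinite(fit.loglik)
    assert np.all(np.isfinite(fit.posteriors))


def test_posterior_accuracy_on_well_separated_states(two_state_pair):
    states, seq, series = two_state_pair
    model = ws.HMMModel(states, ws.TransitionSpec(tau=86400.0, dt=1.0, m=2))
    fit = ws.forward_backward(series, model)
    acc = np.mean(fit.argmax_states == seq)
    assert acc >= 0.95


def test_missing_frames_are_bridged(two_state_pair):
    states, _seq, series = two_state_pair
    import copy
    s2 = copy.deepcopy(series)
    s2.valid[100:140] = False
    model = ws.HMMModel(states, ws.TransitionSpec(tau=300.0, dt=1.0, m=2))
    fit = ws.forward_backward(s2, model)
    assert np.allclose(fit.posteriors[100:140].sum(axis=1), 1.0)
    assert fit.n_valid == s2.n_valid


# ---------------------------------------------------------------------------
# re-estimation


def test_reestimate_with_unit_posteriors_matches_textbook_estimators():
    series = random_series(500, seed=11)
    post = np.ones((500, 1))
    st = ws.reestimate_state(series, post, 0)
    assert st.mu_s == pytest.approx(series.s_hat.mean(), rel=1e-12)
    assert st.var_s == pytest.approx(series.s_hat.var(ddof=1), rel=1e-10)
    assert st.cov_sa == pytest.approx(
        np.cov(series.s_hat, series.a_hat, ddof=1)[0, 1], rel=1e-10
    )
    assert st.var_ar == pytest.approx((series.ar_hat ** 2).mean(), rel=1e-12)
    assert st.p_rev == pytest.approx(series.r.mean(), rel=1e-12)


def test_reestimate_constant_series_hits_variance_floor():
    n = 100
    series = ws.MotionSeries(
        times=np.arange(n, dtype=float), valid=np.ones(n, bool),
        r=np.zeros(n, int), s=np.full(n, 2.0), a_t=np.zeros(n),
        a_r=np.zeros(n), s_hat=np.full(n, 1.44), a_hat=np.zeros(n),
        ar_hat=np.zeros(n),
    )
    st = ws.reestimate_state(series, np.ones((n, 1)), 0, variance_floor=1e-6)
    assert st.mu_s == pytest.approx(1.44)
    assert st.var_s == 1e-6 and st.var_a == 1e-6 and st.var_ar == 1e-6


def test_reestimate_recovers_generating_parameters(two_state_pair):
    states, seq, series = two_state_pair
    post = np.zeros((len(series), 2))
    post[np.arange(len(series)), seq] = 1.0  # oracle assignment
    for j, gen in enumerate(states):
        est = ws.reestimate_state(series, post, j)
        n_j = (seq == j).sum()
        se = np.sqrt(gen.var_s / n_j)
        assert abs(est.mu_s - gen.mu_s) < 5 * se
        assert abs(est.p_rev - gen.p_rev) < 5 * np.sqrt(gen.p_rev * (1 - gen.p_rev) / n_j)


def test_reestimate_transitions():
    T = ws.reestimate_transitions(np.array([[9.0, 1.0], [1.0, 9.0]]))
    assert np.allclose(T, [[0.9, 0.1], [0.1, 0.9]])
    assert np.allclose(ws.reestimate_transitions(np.eye(3)), np.eye(3))
    prior = ws.transition_matrix(ws.TransitionSpec(tau=10, dt=1, m=2))
    T = ws.reestimate_transitions(np.array([[0.0, 0.0], [2.0, 6.0]]),
                                  fallback=prior)
    assert np.allclose(T[0], prior[0])
    assert np.allclose(T[1], [0.25, 0.75])
    with pytest.raises(ValueError):
        ws.reestimate_transitions(np.array([[-1.0, 1.0], [0.0, 1.0]]))


def test_lifetime_recovered_from_transition_counts():
    states = [
        ws.StateDescription(0.05, 0.5, 0.5, 0.05, 0.05, 0.02),
        ws.StateDescription(0.30, 3.0, 1.5, 0.10, 0.10, 0.05),
    ]
    cfg = ws.SimConfig(states=states, lifetimes=100.0, duration=10_000,
                       seed=21)
    seq = ws.simulate_state_sequence(cfg)
    series = ws.simulate_characteristics(states, seq, seed=22)
    model = ws.HMMModel(states, ws.TransitionSpec(tau=100.0, dt=1.0, m=2))
    fit = ws.forward_backward(series, model)
    T = ws.reestimate_transitions(fit.expected_transitions)
    for i in range(2):
        life = 1.0 / (1 - T[i, i])
        assert life == pytest.approx(100.0, rel=0.2)


# ---------------------------------------------------------------------------
# excess entropy


def test_forecaster_excess_entropies():
    fx = ws.forecaster_fixture()
    assert ws.excess_entropy(fx[1]) == pytest.approx(0.0, abs=1e-12)
    assert ws.excess_entropy(fx[2]) == pytest.approx(0.094, abs=5e-4)
    assert ws.excess_entropy(fx[3]) == pytest.approx(0.59, abs=5e-3)


def test_excess_entropy_extremes():
    # constant posteriors carry no time-resolved information
    assert ws.excess_entropy(np.tile([0.3, 0.7], (50, 1))) == pytest.approx(0.0)
    # hard labels with equal occupancy achieve the log2(m) maximum
    hard2 = np.repeat(np.eye(2), 25, axis=0)
    assert ws.excess_entropy(hard2) == pytest.approx(1.0, abs=1e-12)
    hard3 = np.repeat(np.eye(3), 10, axis=0)
    assert ws.excess_entropy(hard3) == pytest.approx(np.log2(3), abs=1e-12)
    assert np.log2(3) == pytest.approx(1.58, abs=5e-3)


def test_excess_entropy_jensen_bounds():
    rng = np.random.default_rng(13)
    for m in (2, 3, 4):
        for _ in range(300):
            p = rng.dirichlet(np.full(m, rng.uniform(0.1, 5.0)),
                              size=rng.integers(2, 60))
            s = ws.excess_entropy(p)
            assert -1e-12 <= s <= np.log2(m) + 1e-12


def test_stronger_penalty_never_increases_switch_count(two_state_pair):
    states, _seq, series = two_state_pair
    switches = []
    for tau in (3.0, 10.0, 100.0, 3000.0, 86400.0):
        model = ws.HMMModel(states, ws.TransitionSpec(tau=tau, dt=1.0, m=2))
        fit = ws.forward_backward(series, model)
        switches.append(int(np.sum(np.diff(fit.argmax_states) != 0)))
    assert all(a >= b for a, b in zip(switches, switches[1:]))
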