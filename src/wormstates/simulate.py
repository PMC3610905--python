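"""Synthetic single-animal tracks and motion-characteristic series.

The generator emulates the recording conditions the analysis is designed
for: 1 Hz centroid sampling at micrometer scale, recordings tens of
minutes to hours long, ~1 um position noise biased along a body axis,
and Markov state switching with lifetimes of tens of seconds to minutes.

Characteristics are drawn from the heavy-tailed family moment-matched to
each :class:`~wormstates.hmm.StateDescription`: a multivariate Student's
t with ``nu - 2`` degrees of freedom and scale ``Sigma (nu-4)/(nu-2)``,
whose covariance is exactly ``Sigma``, so sample moments of the draws
reproduce the state parameters.  Draws violating the magnitude
consistency ``a_hat >= |ar_hat|`` (which every real frame satisfies,
since acceleration magnitude bounds its radial component) are redrawn.

Position tracks are built by chaining reconstructed triples.  Because
consecutive triples share a velocity whose magnitude two independently
drawn frames would both have to prescribe, drawn frames are realized
exactly at alternating interior timepoints; the frames in between are
continuity byproducts.  At zero noise, reducing a simulated track
recovers the drawn characteristics exactly at the realized timepoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import DeskewParams
from .hmm import StateDescription
from .motion import MotionSeries, Track, reconstruct_triple, undeskew, MotionFrame

logger = logging.getLogger("wormstates")

__all__ = [
    "SimConfig",
    "SimulatedTrack",
    "simulate_state_sequence",
    "simulate_characteristics",
    "simulate_track",
    "forecaster_fixture",
    "three_state_example",
]


@dataclass
class SimConfig:
    """Generative settings for one synthetic recording."""

    states: list                      # list[StateDescription]
    lifetimes: list | float           # seconds, per state or common
    duration: float = 1800.0          # s
    dt: float = 1.0                   # s
    position_noise_sd: float = 1.0    # um, along the body axis
    noise_anisotropy: float = 3.0     # major/minor axis ratio, >= 1
    nu: int = 5
    seed: int = 0
    deskew: DeskewParams = field(default_factory=DeskewParams)

    def __post_init__(self) -> None:
        if self.duration / self.dt < 10:
            raise ValueError("need at least 10 timepoints")
        lt = np.atleast_1d(np.asarray(self.lifetimes, float))
        if lt.size == 1:
            lt = np.full(len(self.states), float(lt[0]))
        if lt.size != len(self.states) or np.any(lt <= 0):
            raise ValueError("need one positive lifetime per state")
        self.lifetimes = lt
        if self.noise_anisotropy < 1:
            raise ValueError("noise anisotropy must be >= 1")

    @property
    def n_points(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass
class SimulatedTrack:
    """A synthetic track plus its ground truth."""

    track: Track
    state_seq: np.ndarray          # (N,) generating state per timepoint
    drawn: MotionSeries            # the drawn characteristic frames
    realized_idx: np.ndarray       # interior indices at which drawn frames
    #                                are realized exactly (alternating)
    config: SimConfig = None


# ---------------------------------------------------------------------------
# state sequence


def simulate_state_sequence(config: SimConfig) -> np.ndarray:
    """Markov chain with per-state exit probability 1 - exp(-dt/lifetime)."""
    rng = np.random.default_rng(config.seed)
    m = len(config.states)
    n = config.n_points
    seq = np.empty(n, dtype=int)
    if m == 1:
        seq[:] = 0
        return seq
    p_exit = 1.0 - np.exp(-config.dt / config.lifetimes)
    # stationary distribution of the embedded chain: pi_i ~ lifetime_i
    stat = config.lifetimes / config.lifetimes.sum()
    state = int(rng.choice(m, p=stat))
    t = 0
    while t < n:
        # geometric dwell (support >= 1 step)
        dwell = int(rng.geometric(p_exit[state]))
        seq[t:t + dwell] = state
        t += dwell
        others = [j for j in range(m) if j != state]
        state = int(rng.choice(others))
    return seq


# ---------------------------------------------------------------------------
# characteristic sampling


def _sample_state(
    state: StateDescription, n: int, nu: int, rng: np.random.Generator,
    max_reject_rate: float = 0.5,
):
    """Draw n (s_hat, a_hat, ar_hat) vectors moment-matched to ``state``."""
    k = nu - 2  # dof of the equivalent standard multivariate t
    scale = state.cov * (nu - 4) / (nu - 2)
    L = np.linalg.cholesky(scale)
    mean = state.mean

    def draw(size):
        z = rng.standard_normal((size, 3))
        g = rng.chisquare(k, size=size)
        return mean + (z @ L.T) * np.sqrt(k / g)[:, None]

    x = draw(n)
    n_rejected = 0
    bad = x[:, 1] < np.abs(x[:, 2])  # magnitude consistency a_hat >= |ar_hat|
    for _ in range(200):
        nb = int(bad.sum())
        if nb == 0:
            break
        n_rejected += nb
        x[bad] = draw(nb)
        bad = x[:, 1] < np.abs(x[:, 2])
    rate = n_rejected / max(n_rejected + n, 1)
    if rate > max_reject_rate:
        raise ValueError(
            f"rejection rate {rate:.2f} > {max_reject_rate}: state variances "
            "var_a and var_ar are inconsistent with a_hat >= |ar_hat|"
        )
    return x


def simulate_characteristics(
    states: list,
    state_seq: np.ndarray,
    nu: int = 5,
    seed: int = 0,
    deskew_params: DeskewParams | None = None,
    dt: float = 1.0,
) -> MotionSeries:
    """Sample a motion-characteristic series along a given state sequence.

    The deskewed speed may occasionally be negative (the emission family
    places some mass there, as the fitted density does); such frames are
    legitimate observations for fitting but are not realizable as
    positions.
    """
    params = deskew_params or DeskewParams()
    rng = np.random.default_rng(seed)
    state_seq = np.asarray(state_seq, int)
    n = state_seq.size
    obs = np.empty((n, 3))
    r = np.empty(n, dtype=int)
    for j, st in enumerate(states):
        idx = np.flatnonzero(state_seq == j)
        if idx.size == 0:
            continue
        obs[idx] = _sample_state(st, idx.size, nu, rng)
        r[idx] = rng.random(idx.size) < st.p_rev
    s = undeskew(obs[:, 0], params.s0)
    a_mag = undeskew(obs[:, 1], params.a0)
    a_r = undeskew(obs[:, 2], params.a0)
    a_t = np.sqrt(np.maximum(a_mag ** 2 - a_r ** 2, 0.0))
    a_t *= rng.choice([-1.0, 1.0], size=n)
    times = np.arange(n) * dt
    return MotionSeries(
        times=times,
        valid=np.ones(n, bool),
        r=r,
        s=s,
        a_t=a_t,
        a_r=a_r,
        s_hat=obs[:, 0],
        a_hat=obs[:, 1],
        ar_hat=obs[:, 2],
        deskew_params=params,
    )


# ---------------------------------------------------------------------------
# track synthesis


def _realizable(r, s, a_mag, dt) -> bool:
    if s <= 0:
        return False
    if r == 1:
        return a_mag * dt < 2 * s
    return a_mag * dt <= 2 * s


def _rot(angle: float) -> np.ndarray:
    c, si = np.cos(angle), np.sin(angle)
    return np.array([[c, -si], [si, c]])


def simulate_track(config: SimConfig) -> SimulatedTrack:
    """Synthesize a centroid track realizing drawn frames at alternating
    interior timepoints, then add anisotropic position noise."""
    rng = np.random.default_rng(config.seed)
    seq = simulate_state_sequence(config)
    n = config.n_points
    dt = config.dt
    series = simulate_characteristics(
        config.states, seq, config.nu, int(rng.integers(2 ** 31)),
        config.deskew, dt,
    )
    # redraw unrealizable frames individually (s <= 0 or too-large a)
    for t in range(n):
        tries = 0
        while not _realizable(series.r[t], series.s[t],
                              np.hypot(series.a_t[t], series.a_r[t]), dt):
            x = _sample_state(config.states[seq[t]], 1, config.nu, rng,
                              max_reject_rate=1.0)[0]
            series.s_hat[t], series.a_hat[t], series.ar_hat[t] = x
            series.s[t] = undeskew(x[0], config.deskew.s0)
            a_mag = undeskew(x[1], config.deskew.a0)
            series.a_r[t] = undeskew(x[2], config.deskew.a0)
            at = np.sqrt(max(a_mag ** 2 - series.a_r[t] ** 2, 0.0))
            series.a_t[t] = at if rng.random() < 0.5 else -at
            series.r[t] = int(rng.random() < config.states[seq[t]].p_rev)
            tries += 1
            if tries > 1000:
                raise ValueError("cannot draw a realizable frame; state is "
                                 "inconsistent with positional realization")

    pos = np.zeros((n, 2))
    realized = np.arange(1, n - 1, 2)
    heading = rng.uniform(0, 2 * np.pi)
    for t in realized:
        frame = MotionFrame(int(series.r[t]), float(series.s[t]),
                            float(series.a_t[t]), float(series.a_r[t]))
        if frame.s == 0.0:
            pos[t] = pos[t - 1]
            pos[t + 1] = pos[t - 1]
            continue
        tri = reconstruct_triple(frame, dt)
        v1c = tri[1] - tri[0]
        if t > 1:
            v_prev = pos[t - 1] - pos[t - 2]
            if np.linalg.norm(v_prev) > 0:
                heading = np.arctan2(v_prev[1], v_prev[0])
        R = _rot(heading - np.arctan2(v1c[1], v1c[0]))
        pos[t] = pos[t - 1] + R @ (tri[1] - tri[0])
        pos[t + 1] = pos[t - 1] + R @ (tri[2] - tri[0])
    last = realized[-1] + 1 if realized.size else 0
    if last < n - 1:
        v = pos[last] - pos[last - 1] if last > 0 else np.zeros(2)
        for t in range(last + 1, n):
            pos[t] = pos[t - 1] + v

    if config.position_noise_sd > 0:
        psi = rng.uniform(0, 2 * np.pi)  # body-axis direction, fixed per track
        axis = np.array([np.cos(psi), np.sin(psi)])
        perp = np.array([-axis[1], axis[0]])
        sd_major = config.position_noise_sd
        sd_minor = config.position_noise_sd / config.noise_anisotropy
        noise = (rng.standard_normal((n, 1)) * sd_major * axis
                 + rng.standard_normal((n, 1)) * sd_minor * perp)
        pos = pos + noise

    track = Track(times=np.arange(n) * dt, positions=pos,
                  valid=np.ones(n, bool))
    drawn = MotionSeries(
        times=series.times[realized], valid=np.ones(realized.size, bool),
        r=series.r[realized], s=series.s[realized],
        a_t=series.a_t[realized], a_r=series.a_r[realized],
        s_hat=series.s_hat[realized], a_hat=series.a_hat[realized],
        ar_hat=series.ar_hat[realized], deskew_params=config.deskew,
    )
    return SimulatedTrack(track=track, state_seq=seq, drawn=drawn,
                          realized_idx=realized, config=config)


# ---------------------------------------------------------------------------
# worked-example fixtures and canonical study states


def forecaster_fixture() -> dict[int, np.ndarray]:
    """Posterior matrices for the three-forecaster worked example.

    7-day, two-state ('rain'/'dry') posterior sequences: forecaster 1
    predicts 1/7 every day, forecaster 2 predicts 1/12 on six days and
    1/2 on one, forecaster 3 predicts 0 on six days and 1 on one.  All
    three are statistically accurate; their excess entropies are 0,
    0.094 and 0.59 bits/day.
    """
    def mat(ps):
        ps = np.asarray(ps, float)
        return np.column_stack([ps, 1.0 - ps])

    return {
        1: mat([1 / 7] * 7),
        2: mat([1 / 12] * 6 + [1 / 2]),
        3: mat([0.0] * 6 + [1.0]),
    }


def three_state_example() -> tuple[list, np.ndarray]:
    """Canonical well-separated roaming/dwelling/quiescence triplet.

    Deskewed units: roaming moves fast (~20 um/s) with rare reversals;
    dwelling is slower with frequent reversals and correlated speed and
    acceleration; quiescence is near-immobile with small variances.
    Lifetimes are in the observed 1-2 minute range.
    """
    states = [
        StateDescription(p_rev=0.02, mu_s=3.7, mu_a=1.5, var_s=0.15,
                         var_a=0.15, var_ar=0.10, cov_sa=0.0,
                         label="roaming"),
        StateDescription(p_rev=0.30, mu_s=2.6, mu_a=1.2, var_s=0.20,
                         var_a=0.15, var_ar=0.08, cov_sa=0.10,
                         label="dwelling"),
        StateDescription(p_rev=0.05, mu_s=0.25, mu_a=0.25, var_s=0.02,
                         var_a=0.02, var_ar=0.005, cov_sa=0.0,
                         label="quiescence"),
    ]
    lifetimes = np.array([90.0, 60.0, 120.0])
    return states, lifetimes
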