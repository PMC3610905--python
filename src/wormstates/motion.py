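"""Motion reduction: centroid triples -> rotation/translation-invariant characteristics.

Three consecutive center-of-mass positions carry six degrees of freedom,
three of which only describe where the dish sits under the camera.  The
remaining three numbers' worth of information is captured by a reversal
bit ``r``, a speed ``s`` and an acceleration two-vector ``a = (a_t, a_r)``
expressed in a frame aligned with the animal's direction of motion:

* velocities ``v1 = (p2 - p1)/dt`` and ``v2 = (p3 - p2)/dt``;
* ``u = v1 + v2`` and ``w = v2 - v1``;
* if ``|w| > |u|`` the step is a reversal (``r = 1``, equivalently the
  heading changed by more than 90 degrees); the direction vector is then
  ``v1 - v2`` and the laboratory-frame acceleration is ``u/dt``;
  otherwise ``r = 0``, the direction vector is ``u`` and the acceleration
  is the conventional ``w/dt``;
* ``s`` is half the length of the direction vector (the mean-velocity
  magnitude for a non-reversal);
* ``a`` is the laboratory acceleration rotated into the frame whose x
  axis is the unit direction vector, with the first row of the rotation
  negated in the reversal branch.  This branched definition makes both
  components of ``a`` continuous across the branch switch, and makes the
  map positions -> (r, s, a) exactly invertible up to rigid motion.

Speed and acceleration magnitudes are strongly right-skewed; they are
deskewed with ``asinh(x / x0)``, which is linear for ``|x| << x0`` (where
measurement noise dominates) and logarithmic for ``x >> x0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .config import DeskewParams

logger = logging.getLogger("wormstates")

__all__ = [
    "Track",
    "MotionFrame",
    "MotionSeries",
    "reduce_triple",
    "reduce_track",
    "deskew",
    "undeskew",
    "reconstruct_triple",
    "scramble_series",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class Track:
    """A single-animal centroid track: times (s), positions (um), gap mask."""

    times: np.ndarray          # (N,) seconds, strictly increasing
    positions: np.ndarray      # (N, 2) um; may be NaN where invalid
    valid: np.ndarray          # (N,) bool

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.times.ndim != 1 or self.positions.shape != (self.times.size, 2):
            raise ValueError("times must be (N,), positions (N, 2)")
        if self.valid.shape != self.times.shape:
            raise ValueError("valid mask must match times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.positions[self.valid])):
            raise ValueError("positions must be finite where valid")

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def median_dt(self) -> float:
        return float(np.median(np.diff(self.times)))


class MotionFrame(NamedTuple):
    """Invariant description of one centroid triple."""

    r: int          # reversal flag
    s: float        # speed, um/s
    a_t: float      # tangential acceleration, um/s^2
    a_r: float      # radial acceleration, um/s^2
    degenerate: bool = False

    @property
    def a_mag(self) -> float:
        return float(np.hypot(self.a_t, self.a_r))


@dataclass
class MotionSeries:
    """Per-timepoint motion characteristics plus their deskewed versions."""

    times: np.ndarray      # (N,) s
    valid: np.ndarray      # (N,) bool; False = frame touches a gap
    r: np.ndarray          # (N,) {0,1}
    s: np.ndarray          # (N,) um/s
    a_t: np.ndarray        # (N,) um/s^2
    a_r: np.ndarray        # (N,) um/s^2
    s_hat: np.ndarray      # deskewed speed
    a_hat: np.ndarray      # deskewed acceleration magnitude
    ar_hat: np.ndarray     # deskewed radial acceleration (signed)
    degenerate: np.ndarray = None  # (N,) bool, all-identical triples
    deskew_params: DeskewParams = field(default_factory=DeskewParams)

    def __post_init__(self) -> None:
        if self.degenerate is None:
            self.degenerate = np.zeros(self.times.shape, dtype=bool)

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))

    @property
    def a_mag(self) -> np.ndarray:
        return np.hypot(self.a_t, self.a_r)

    def observations(self) -> np.ndarray:
        """(N, 3) deskewed continuous observation vectors (s_hat, a_hat, ar_hat)."""
        return np.column_stack([self.s_hat, self.a_hat, self.ar_hat])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "r": self.r,
                "s": self.s,
                "a_t": self.a_t,
                "a_r": self.a_r,
                "s_hat": self.s_hat,
                "a_hat": self.a_hat,
                "ar_hat": self.ar_hat,
                "valid": self.valid.astype(int),
            }
        )

    @classmethod
    def from_arrays(
        cls,
        times: np.ndarray,
        r: np.ndarray,
        s: np.ndarray,
        a_t: np.ndarray,
        a_r: np.ndarray,
        params: DeskewParams | None = None,
        valid: np.ndarray | None = None,
        degenerate: np.ndarray | None = None,
    ) -> "MotionSeries":
        params = params or DeskewParams()
        times = np.asarray(times, float)
        s = np.asarray(s, float)
        a_t = np.asarray(a_t, float)
        a_r = np.asarray(a_r, float)
        a_mag = np.hypot(a_t, a_r)
        if valid is None:
            valid = np.ones(times.shape, bool)
        return cls(
            times=times,
            valid=np.asarray(valid, bool),
            r=np.asarray(r, int),
            s=s,
            a_t=a_t,
            a_r=a_r,
            s_hat=deskew(s, params.s0),
            a_hat=deskew(a_mag, params.a0),
            ar_hat=deskew(a_r, params.a0),
            degenerate=degenerate,
            deskew_params=params,
        )


# ---------------------------------------------------------------------------
# deskewing


def deskew(x, x0: float):
    """asinh(x / x0): odd, strictly increasing, linear near 0, log for large x."""
    if x0 <= 0:
        raise ValueError("deskew offset must be positive")
    return np.arcsinh(np.asarray(x, dtype=float) / x0)


def undeskew(y, x0: float):
    """Inverse of :func:`deskew`."""
    if x0 <= 0:
        raise ValueError("deskew offset must be positive")
    return np.sinh(np.asarray(y, dtype=float)) * x0


# ---------------------------------------------------------------------------
# reduction


def _reduce_vectors(v1: np.ndarray, v2: np.ndarray, dt: float):
    """Vectorized branch of the reduction; v1, v2 are (N, 2) velocities."""
    u = v1 + v2
    w = v2 - v1
    nu_ = np.linalg.norm(u, axis=1)
    nw = np.linalg.norm(w, axis=1)
    rev = nw > nu_  # strict: reversal iff heading change > 90 degrees

    # direction vector D and laboratory acceleration alpha per branch
    D = np.where(rev[:, None], v1 - v2, u)
    alpha = np.where(rev[:, None], u, w) / dt
    nD = np.linalg.norm(D, axis=1)
    s = nD / 2.0

    degen = nD == 0.0  # only when all three points coincide
    safe = np.where(degen, 1.0, nD)
    d = D / safe[:, None]

    # rotate alpha into the frame whose x axis is d; in the reversal branch
    # the first row of the rotation is negated, which together with the
    # D = v1 - v2 convention keeps both a_t and a_r continuous at the switch
    sign = np.where(rev, -1.0, 1.0)
    a_t = sign * (d[:, 0] * alpha[:, 0] + d[:, 1] * alpha[:, 1])
    a_r = -d[:, 1] * alpha[:, 0] + d[:, 0] * alpha[:, 1]

    a_t = np.where(degen, 0.0, a_t)
    a_r = np.where(degen, 0.0, a_r)
    r = np.where(degen, 0, rev.astype(int))
    return r, s, a_t, a_r, degen


def reduce_triple(p1, p2, p3, dt: float = 1.0) -> MotionFrame:
    """Reduce three consecutive positions to a :class:`MotionFrame`.

    A triple of identical points yields the degenerate zero frame; a triple
    in which the animal exactly reverses (p3 == p1) is a reversal with zero
    acceleration.
    """
    pts = np.asarray([p1, p2, p3], dtype=float)
    if pts.shape != (3, 2) or not np.all(np.isfinite(pts)):
        raise ValueError("need three finite 2-D positions")
    if dt <= 0:
        raise ValueError("dt must be positive")
    v1 = (pts[1] - pts[0])[None, :] / dt
    v2 = (pts[2] - pts[1])[None, :] / dt
    r, s, a_t, a_r, degen = _reduce_vectors(v1, v2, dt)
    return MotionFrame(int(r[0]), float(s[0]), float(a_t[0]), float(a_r[0]),
                       bool(degen[0]))


def reduce_track(
    track: Track,
    dt: float | None = None,
    params: DeskewParams | None = None,
    dt_slack: float = 0.1,
) -> MotionSeries:
    """Reduce a whole track to a :class:`MotionSeries`.

    One frame is produced per interior timepoint whose two neighbors are
    valid and whose two frame intervals are within ``dt_slack`` (fraction)
    of the nominal ``dt``; all other frames are marked invalid.
    """
    params = params or DeskewParams()
    if dt is None:
        dt = track.median_dt
    n = len(track)
    if n < 3 or np.count_nonzero(track.valid) < 3:
        logger.warning("track too short for motion reduction (<3 valid points)")
        empty = np.empty(0)
        return MotionSeries.from_arrays(empty, empty.astype(int), empty, empty,
                                        empty, params)

    t = track.times
    p = track.positions
    ok_pts = track.valid
    # interior frames: indices 1..n-2
    idx = np.arange(1, n - 1)
    dt1 = t[idx] - t[idx - 1]
    dt2 = t[idx + 1] - t[idx]
    spacing_ok = (np.abs(dt1 - dt) <= dt_slack * dt) & (np.abs(dt2 - dt) <= dt_slack * dt)
    valid = ok_pts[idx - 1] & ok_pts[idx] & ok_pts[idx + 1] & spacing_ok

    v1 = np.zeros((idx.size, 2))
    v2 = np.zeros((idx.size, 2))
    vi = valid
    v1[vi] = (p[idx[vi]] - p[idx[vi] - 1]) / dt
    v2[vi] = (p[idx[vi] + 1] - p[idx[vi]]) / dt
    r, s, a_t, a_r, degen = _reduce_vectors(v1, v2, dt)
    r[~vi] = 0
    s[~vi] = 0.0
    a_t[~vi] = 0.0
    a_r[~vi] = 0.0
    degen = degen & vi
    series = MotionSeries.from_arrays(t[idx], r, s, a_t, a_r, params,
                                      valid=valid, degenerate=degen)
    logger.debug(
        "reduced track: %d frames, %d valid, %.3f gap fraction",
        len(series), series.n_valid, 1 - series.n_valid / max(len(series), 1),
    )
    return series


# ---------------------------------------------------------------------------
# reconstruction (inverse reduction)


def reconstruct_triple(frame: MotionFrame, dt: float = 1.0) -> np.ndarray:
    """Positions (3, 2) realizing ``frame``, canonically placed.

    The first point is at the origin and the branch direction vector lies
    along +x.  Requires a realizable frame: ``s > 0`` (unless the frame is
    the all-zero one) and ``a_mag * dt <= 2 s`` (strictly for a reversal).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    r, s, a_t, a_r = frame.r, frame.s, frame.a_t, frame.a_r
    a_mag = np.hypot(a_t, a_r)
    if s == 0.0:
        if a_mag > 0:
            raise ValueError("s = 0 with nonzero acceleration is not realizable")
        return np.zeros((3, 2))
    if r == 1:
        if a_mag * dt >= 2 * s:
            raise ValueError("reversal frame requires a_mag * dt < 2 s")
        u = dt * np.array([-a_t, a_r])
        w = np.array([-2.0 * s, 0.0])
    else:
        if a_mag * dt > 2 * s:
            raise ValueError("non-reversal frame requires a_mag * dt <= 2 s")
        u = np.array([2.0 * s, 0.0])
        w = dt * np.array([a_t, a_r])
    v1 = (u - w) / 2.0
    v2 = (u + w) / 2.0
    p1 = np.zeros(2)
    p2 = p1 + v1 * dt
    p3 = p2 + v2 * dt
    return np.vstack([p1, p2, p3])


# ---------------------------------------------------------------------------
# scrambling (temporal-structure control)


def scramble_series(series: MotionSeries, seed: int) -> MotionSeries:
    """Uniformly permute the valid frames of a series (invalid slots stay put).

    Destroys temporal ordering while preserving every marginal histogram;
    used as the null control for excess-entropy comparisons.
    """
    rng = np.random.default_rng(seed)
    idx = np.flatnonzero(series.valid)
    perm = rng.permutation(idx.size)

    def _p(x):
        out = np.array(x, copy=True)
        out[idx] = out[idx][perm]
        return out

    return MotionSeries(
        times=series.times.copy(),
        valid=series.valid.copy(),
        r=_p(series.r),
        s=_p(series.s),
        a_t=_p(series.a_t),
        a_r=_p(series.a_r),
        s_hat=_p(series.s_hat),
        a_hat=_p(series.a_hat),
        ar_hat=_p(series.ar_hat),
        degenerate=_p(series.degenerate),
        deskew_params=series.deskew_params,
    )
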