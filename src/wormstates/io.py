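"""Readers, writers, track segmentation and the end-to-end pipeline.

Tracks travel as delimited text with columns ``time_s, x_um, y_um``
(missing frames as absent rows or NaN).  Fits are written as a CSV of
per-time state probabilities plus a JSON sidecar holding the state
parameters, lifetime, tail parameter, likelihood and excess entropy.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .dissimilarity import metricize, mds_embed, pairwise_dissimilarity
from .geometry import StateCloud, triangularity_test, weighted_pca
from .hmm import FitResult, StateDescription, PARAM_NAMES
from .motion import MotionSeries, Track, reduce_track
from .protocols import UnbiasedFit, unbiased_fit

logger = logging.getLogger("wormstates")

__all__ = [
    "read_track",
    "write_track",
    "cut_track",
    "write_motion",
    "write_fit",
    "write_state_table",
    "read_state_table",
    "pipeline",
]

TRACK_COLUMNS = ("time_s", "x_um", "y_um")


def read_track(path: str | Path, dialect: str | None = None) -> Track:
    """Read a centroid track from delimited text (header required)."""
    sep = {"csv": ",", "tsv": "\t", None: None}.get(dialect, dialect)
    if sep is None:
        suffix = Path(path).suffix.lower()
        sep = {".csv": ",", ".tsv": "\t"}.get(suffix)
    if sep is None:
        df = pd.read_csv(path, sep=None, engine="python")
    else:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing columns {sorted(missing)}; expected {TRACK_COLUMNS}"
        )
    times = df["time_s"].to_numpy(float)
    if np.any(~np.isfinite(times)) or np.any(np.diff(times) <= 0):
        raise ValueError(f"{path}: time_s must be finite and strictly increasing")
    pos = df[["x_um", "y_um"]].to_numpy(float)
    valid = np.all(np.isfinite(pos), axis=1)
    track = Track(times=times, positions=pos, valid=valid)
    logger.info(
        "read %s: %d points over %.0f s, gap fraction %.3f",
        path, len(track), track.duration, 1 - valid.mean(),
    )
    return track


def write_track(track: Track, path: str | Path) -> None:
    pos = np.where(track.valid[:, None], track.positions, np.nan)
    pd.DataFrame(
        {"time_s": track.times, "x_um": pos[:, 0], "y_um": pos[:, 1]}
    ).to_csv(path, index=False, float_format="%.17g")


def cut_track(track: Track, cut_length_s: float = 900.0) -> list[Track]:
    """Contiguous non-overlapping cuts (half-open [start, start+L) windows)."""
    if cut_length_s <= 0:
        raise ValueError("cut length must be positive")
    t0 = track.times[0]
    total = track.times[-1] - t0
    n_cuts = max(int(np.ceil(total / cut_length_s - 1e-9)), 1)
    if total < cut_length_s:
        logger.warning("track (%.0f s) shorter than one cut (%.0f s)",
                       total, cut_length_s)
    cuts = []
    for k in range(n_cuts):
        lo = t0 + k * cut_length_s
        hi = lo + cut_length_s
        mask = (track.times >= lo) & (track.times < hi)
        if k == n_cuts - 1:  # final cut keeps any ragged tail
            mask = track.times >= lo
        if not mask.any():
            continue
        cuts.append(Track(track.times[mask], track.positions[mask],
                          track.valid[mask]))
    return cuts


def write_motion(series: MotionSeries, path: str | Path) -> None:
    series.to_dataframe().to_csv(path, index=False)


def _state_to_dict(s: StateDescription) -> dict:
    d = {k: getattr(s, k) for k in PARAM_NAMES}
    d.update(pi=s.pi, label=s.label)
    return d


def write_fit(fit: FitResult, prefix: str | Path, times=None,
              config: RunConfig | None = None) -> None:
    """CSV of posteriors (+ argmax) and a JSON sidecar of model metadata."""
    prefix = Path(prefix)
    m = fit.posteriors.shape[1]
    cols = {f"p_state{j + 1}": fit.posteriors[:, j] for j in range(m)}
    df = pd.DataFrame(cols)
    if times is not None:
        df.insert(0, "time_s", np.asarray(times, float))
    df["argmax"] = fit.argmax_states + 1
    df.to_csv(prefix.with_suffix(".csv"), index=False)
    meta = {
        "states": [_state_to_dict(s) for s in fit.model.states],
        "tau_s": fit.model.transition.tau,
        "dt_s": fit.model.transition.dt,
        "nu": fit.model.nu,
        "loglik_per_point_nats": fit.loglik_per_point,
        "excess_entropy_bits": fit.excess_entropy_bits,
        "expected_transitions": fit.expected_transitions.tolist(),
        "n_valid": fit.n_valid,
        "converged": fit.converged,
    }
    if config is not None:
        meta["config_digest"] = config.digest()
        meta["seed"] = config.seed
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def write_state_table(rows: list[dict], path: str | Path) -> None:
    """State cloud as CSV: 7 parameters + probability + provenance ids."""
    pd.DataFrame(rows).to_csv(path, index=False)


def read_state_table(path: str | Path) -> StateCloud:
    df = pd.read_csv(path)
    pts = df[list(PARAM_NAMES)].to_numpy(float)
    w = df["pi"].to_numpy(float)
    ids = list(zip(df.get("experiment", [""] * len(df)),
                   df.get("track", [""] * len(df)),
                   df.get("state", range(len(df)))))
    return StateCloud(points=pts, weights=w, ids=ids)


# ---------------------------------------------------------------------------
# end-to-end pipeline


def pipeline(
    track_paths: list[str | Path],
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> Path:
    """reduce -> unbiased fit -> state table -> geometry -> dissimilarity/MDS.

    Per-track failures are isolated: the run continues and failures are
    listed in the run summary.  Rerunning with the same config and seed
    reproduces the outputs.
    """
    config = config or RunConfig()
    if not track_paths:
        raise ValueError("no tracks given")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failures = {}
    fitted = []  # (name, series, UnbiasedFit)
    for p in track_paths:
        name = Path(p).stem
        try:
            track = read_track(p)
            series = reduce_track(track, config.dt_s, config.deskew)
            write_motion(series, out / f"{name}.motion.csv")
            ufit = unbiased_fit(
                series, config.tau_s, config.dt_s, nu=config.nu,
                split_eps=config.split_eps, tol=config.tol,
                max_iter=config.max_iter, variance_floor=config.variance_floor,
            )
            write_fit(ufit.best, out / f"{name}.fit", times=series.times,
                      config=config)
            fitted.append((name, series, ufit))
            logger.info(
                "%s: %d valid frames, m=%d, excess entropy %.3f bits",
                name, series.n_valid, ufit.best_m,
                ufit.best.excess_entropy_bits,
            )
        except Exception as exc:
            logger.error("track %s failed: %s", name, exc)
            failures[name] = str(exc)
    if not fitted:
        raise RuntimeError(f"all tracks failed: {failures}")

    rows = []
    for name, _series, ufit in fitted:
        for j, st in enumerate(ufit.best_states):
            row = _state_to_dict(st)
            row.update(track=name, state=j)
            rows.append(row)
    write_state_table(rows, out / "states.csv")

    geometry_result = {}
    if len(rows) >= 4:
        cloud = StateCloud(
            points=np.array([[r[k] for k in PARAM_NAMES] for r in rows]),
            weights=np.array([r["pi"] for r in rows]),
        )
        comps, scores, fracs = weighted_pca(cloud, 2)
        np.savetxt(out / "pca_scores.csv", scores, delimiter=",",
                   header="pc1,pc2", comments="")
        tri = triangularity_test(scores, n_perm=min(config.n_perm, 1000),
                                 seed=config.seed)
        geometry_result = {
            "t_ratio": tri.t_ratio,
            "p_value": tri.p_value,
            "variance_fractions": fracs[:2].tolist(),
        }

    entries = [(series, ufit.best.model, ufit.best)
               for _n, series, ufit in fitted]
    ids = [n for n, _s, _u in fitted]
    D = pairwise_dissimilarity(entries, kind="fit", ids=ids)
    pd.DataFrame(D.values, index=ids, columns=ids).to_csv(
        out / "dissimilarity.csv")
    mds_meta = {}
    if len(fitted) >= 3:
        G, c = metricize(D)
        emb = mds_embed(G, k=2, seed=config.seed)
        pd.DataFrame(emb.locations, index=ids, columns=["x", "y"]).to_csv(
            out / "mds.csv")
        mds_meta = {"stress": emb.stress, "c_offset": c}

    summary = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "tracks": {
            n: {
                "n_valid": s.n_valid,
                "m": u.best_m,
                "excess_entropy_bits": u.best.excess_entropy_bits,
                "pi": [st.pi for st in u.best_states],
            }
            for n, s, u in fitted
        },
        "failures": failures,
        "geometry": geometry_result,
        "mds": mds_meta,
        "config": config.to_dict(),
    }
    with open(out / "run.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return out
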