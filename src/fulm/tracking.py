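"""Linking microbubble detections into tracks and rasterizing them.

Consecutive-frame detections are paired by minimal total Euclidean
distance (linear assignment) under a hard gate: no link may exceed the
distance a bubble can travel in one frame period at the maximum speed
(100 mm/s by default, i.e. 100 um at 1 kHz). There is no gap filling; a
missed frame terminates the track. Tracks shorter than ``min_len`` frames
(10 by default) are discarded. Interframe velocities are finite
differences scaled by the frame rate; each track is finally linearly
interpolated so that every super-resolved pixel crossed by the bubble path
is counted exactly once per traversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .grids import Grid

#: default maximum bubble speed (mm/s) for the linking gate
MAX_SPEED_MM_S = 100.0
#: default minimum track length in successive frames
MIN_TRACK_LEN = 10

TRACKSET_COLUMNS = ["track_id", "frame", "t_s", "z_um", "x_um", "vz_mm_s", "vx_mm_s", "speed_mm_s"]
RASTER_COLUMNS = ["track_id", "iz", "ix", "t_s", "vz_mm_s", "vx_mm_s", "speed_mm_s"]


@dataclass
class TrackSet:
    """Per-bubble trajectories on the frame clock.

    ``df`` columns: track_id, frame, t_s, z_um, x_um, vz_mm_s, vx_mm_s,
    speed_mm_s (one row per detection; per-step velocity is attached to the
    step's first detection, the last detection repeats the previous step).
    """

    df: pd.DataFrame
    frame_rate: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ("track_id", "t_s", "z_um", "x_um") if c not in self.df.columns]
        if missing:
            raise ValueError(f"TrackSet missing columns: {missing}")

    @property
    def n_tracks(self) -> int:
        return int(self.df["track_id"].nunique())

    def groupby_track(self):
        return self.df.groupby("track_id", sort=True)


def gate_distance_um(max_speed_mm_s: float, frame_rate: float) -> float:
    """Maximal linking distance in um for one frame period."""
    return max_speed_mm_s * 1e3 / frame_rate


def link_frames(
    pos0: np.ndarray,
    pos1: np.ndarray,
    max_speed_mm_s: float = MAX_SPEED_MM_S,
    frame_rate: float = 1000.0,
) -> tuple[np.ndarray, float]:
    """One-to-one assignment between two consecutive detection sets.

    ``pos0``/``pos1`` are (N, 2) arrays of (z, x) um. Minimizes the total
    Euclidean distance of matched pairs plus the gate distance for every
    unmatched detection (dummy-node padding at gate cost); pairs farther
    apart than the gate are forbidden. Returns (pairs (m, 2) of indices,
    objective value).
    """
    p0 = np.atleast_2d(np.asarray(pos0, dtype=float))
    p1 = np.atleast_2d(np.asarray(pos1, dtype=float))
    n0 = 0 if p0.size == 0 else p0.shape[0]
    n1 = 0 if p1.size == 0 else p1.shape[0]
    gate = gate_distance_um(max_speed_mm_s, frame_rate)
    if n0 == 0 or n1 == 0:
        return np.empty((0, 2), dtype=int), gate * (n0 + n1)

    d = np.linalg.norm(p0[:, None, :] - p1[None, :, :], axis=2)
    big = 1e9
    n = n0 + n1
    cost = np.zeros((n, n))
    cost[:n0, :n1] = np.where(d <= gate, d, big)
    cost[:n0, n1:] = big
    cost[n0:, :n1] = big
    cost[np.arange(n0), np.arange(n1, n)] = gate  # detection i unmatched
    cost[np.arange(n0, n), np.arange(n1)] = gate  # detection j unmatched
    rows, cols = linear_sum_assignment(cost)
    pairs = [(r, c) for r, c in zip(rows, cols) if r < n0 and c < n1 and d[r, c] <= gate]
    pairs = np.array(sorted(pairs), dtype=int).reshape(-1, 2)
    total = float(sum(d[r, c] for r, c in pairs) + gate * ((n0 - len(pairs)) + (n1 - len(pairs))))
    return pairs, total


def assignment_cost_bruteforce(
    pos0: np.ndarray,
    pos1: np.ndarray,
    max_speed_mm_s: float = MAX_SPEED_MM_S,
    frame_rate: float = 1000.0,
) -> float:
    """Exhaustive-enumeration minimum of the link_frames objective.

    Independent oracle for small instances: enumerates every one-to-one
    matching within the gate and returns the minimal total cost (matched
    distances + gate per unmatched detection).
    """
    from itertools import combinations, permutations

    p0 = np.atleast_2d(np.asarray(pos0, dtype=float))
    p1 = np.atleast_2d(np.asarray(pos1, dtype=float))
    n0 = 0 if p0.size == 0 else p0.shape[0]
    n1 = 0 if p1.size == 0 else p1.shape[0]
    gate = gate_distance_um(max_speed_mm_s, frame_rate)
    if n0 == 0 or n1 == 0:
        return gate * (n0 + n1)
    d = np.linalg.norm(p0[:, None, :] - p1[None, :, :], axis=2)
    best = gate * (n0 + n1)  # nothing matched
    for m in range(1, min(n0, n1) + 1):
        for sub0 in combinations(range(n0), m):
            for sub1 in permutations(range(n1), m):
                dd = d[list(sub0), list(sub1)]
                if np.any(dd > gate):
                    continue
                total = dd.sum() + gate * ((n0 - m) + (n1 - m))
                best = min(best, float(total))
    return best


def compute_velocities(positions_um: np.ndarray, frame_rate: float) -> np.ndarray:
    """Per-step (vz, vx) in mm/s from successive positions (n, 2) um."""
    positions_um = np.asarray(positions_um, dtype=float)
    if len(positions_um) < 2:
        raise ValueError("velocity needs at least 2 positions")
    return np.diff(positions_um, axis=0) * frame_rate / 1e3


def assemble_and_filter(
    detections: pd.DataFrame,
    frame_rate: float,
    max_speed_mm_s: float = MAX_SPEED_MM_S,
    min_len: int = MIN_TRACK_LEN,
) -> TrackSet:
    """Link per-frame detections into tracks and filter by length.

    ``detections`` must carry t_s, z_um, x_um (frame index is recovered
    from t_s on the frame clock). Tracks are grown with no gap filling:
    a detection missing for one frame splits the trajectory into fragments
    filtered independently. Tracks shorter than ``min_len`` successive
    frames are discarded and velocities are attached.
    """
    det = detections.copy()
    det["frame"] = np.round(det["t_s"].to_numpy() * frame_rate).astype(np.int64)
    det = det.sort_values(["frame", "z_um", "x_um"], kind="stable").reset_index(drop=True)
    frames = det["frame"].to_numpy()
    by_frame = {f: np.flatnonzero(frames == f) for f in np.unique(frames)}
    all_frames = sorted(by_frame)

    tracks: list[list[int]] = []
    open_tracks: dict[int, int] = {}  # detection row index in current frame -> track list index
    prev_frame = None
    for f in all_frames:
        idx = by_frame[f]
        if prev_frame is None or f != prev_frame + 1:
            open_tracks = {}
            pairs = np.empty((0, 2), dtype=int)
        else:
            prev_idx = by_frame[prev_frame]
            p0 = det.loc[prev_idx, ["z_um", "x_um"]].to_numpy()
            p1 = det.loc[idx, ["z_um", "x_um"]].to_numpy()
            pairs, _ = link_frames(p0, p1, max_speed_mm_s, frame_rate)
        new_open: dict[int, int] = {}
        linked_from = {int(a): int(b) for a, b in pairs}
        for local0, local1 in linked_from.items():
            if local0 in open_tracks:
                t = open_tracks[local0]
            else:
                tracks.append([int(by_frame[prev_frame][local0])])
                t = len(tracks) - 1
            tracks[t].append(int(idx[local1]))
            new_open[local1] = t
        open_tracks = new_open
        prev_frame = f

    rows = []
    tid = 0
    for members in tracks:
        if len(members) < min_len:
            continue
        sub = det.loc[members]
        pos = sub[["z_um", "x_um"]].to_numpy()
        v = compute_velocities(pos, frame_rate)
        v = np.vstack([v, v[-1]])  # last point repeats the final step velocity
        speed = np.hypot(v[:, 0], v[:, 1])
        if np.any(speed[:-1] > max_speed_mm_s + 1e-9):
            continue  # hard gate; cannot occur with gated linking
        rows.append(
            pd.DataFrame(
                {
                    "track_id": tid,
                    "frame": sub["frame"].to_numpy(),
                    "t_s": sub["t_s"].to_numpy(),
                    "z_um": pos[:, 0],
                    "x_um": pos[:, 1],
                    "vz_mm_s": v[:, 0],
                    "vx_mm_s": v[:, 1],
                    "speed_mm_s": speed,
                }
            )
        )
        tid += 1
    df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame({c: pd.Series(dtype=float) for c in TRACKSET_COLUMNS})
    )
    return TrackSet(
        df=df,
        frame_rate=frame_rate,
        params={"max_speed_mm_s": max_speed_mm_s, "min_len": min_len},
    )


def _segment_crossings(a: np.ndarray, b: np.ndarray, grid: Grid) -> tuple[np.ndarray, np.ndarray]:
    """Exact pixel traversal of the straight segment a -> b.

    Enumerates every gridline crossing, so pixels clipped only at a corner
    are still counted. Returns (pixels (m, 2), fractional parameter of each
    pixel's interval midpoint along the segment).
    """
    ts = [0.0, 1.0]
    for axis, pitch in ((0, grid.pitch_z_um), (1, grid.pitch_x_um)):
        lo, hi = sorted((a[axis], b[axis]))
        k0 = int(np.ceil(lo / pitch))
        k1 = int(np.floor(hi / pitch))
        if k1 >= k0 and b[axis] != a[axis]:
            ks = np.arange(k0, k1 + 1) * pitch
            ts.extend(((ks - a[axis]) / (b[axis] - a[axis])).tolist())
    ts = np.unique(np.clip(ts, 0.0, 1.0))
    mids = 0.5 * (ts[:-1] + ts[1:])
    mids = mids[np.diff(ts) > 1e-12]
    # the endpoints are actual detections: include their pixels even when
    # they sit exactly on a boundary (zero-length interval there)
    mids = np.concatenate([[0.0], mids, [1.0]])
    pts = a[None, :] + mids[:, None] * (b - a)[None, :]
    iz, ix = grid.pos_to_index(pts[:, 0], pts[:, 1])
    pix = np.column_stack([iz, ix])
    keep = np.ones(len(pix), dtype=bool)
    keep[1:] = np.any(pix[1:] != pix[:-1], axis=1)
    return pix[keep], mids[keep]


def rasterize_polyline(points_um: np.ndarray, grid: Grid) -> np.ndarray:
    """Pixel indices (m, 2) crossed by a polyline, once per traversal.

    Exact gridline-crossing enumeration per segment; consecutive
    duplicates are collapsed, so a pixel re-entered in a later traversal
    (U-turn) counts again while continuation across vertices does not.
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    if len(pts) == 1:
        iz, ix = grid.pos_to_index(pts[0, 0], pts[0, 1])
        return np.array([[int(iz), int(ix)]])
    chunks = []
    for a, b in zip(pts[:-1], pts[1:]):
        pix, _ = _segment_crossings(a, b, grid)
        chunks.append(pix)
    pix = np.vstack(chunks)
    keep = np.ones(len(pix), dtype=bool)
    keep[1:] = np.any(pix[1:] != pix[:-1], axis=1)
    return pix[keep]


def rasterize_track(track: pd.DataFrame, grid: Grid) -> pd.DataFrame:
    """Linear spatial interpolation of one track onto the super grid.

    Every pixel crossed between two successive detections is counted once,
    carrying a linearly interpolated timestamp and the local (per-step)
    velocity. Returns columns iz, ix, t_s, vz_mm_s, vx_mm_s, speed_mm_s.
    """
    sub = track.sort_values("t_s", kind="stable")
    pos = sub[["z_um", "x_um"]].to_numpy()
    t = sub["t_s"].to_numpy()
    vz = sub["vz_mm_s"].to_numpy()
    vx = sub["vx_mm_s"].to_numpy()

    out_pix: list[np.ndarray] = []
    out_t: list[np.ndarray] = []
    out_v: list[np.ndarray] = []
    last_pix = None
    if len(pos) == 1:
        segments = []
    else:
        segments = list(zip(pos[:-1], pos[1:], t[:-1], t[1:], vz[:-1], vx[:-1]))
    for a, b, ta, tb, svz, svx in segments:
        pix, mids = _segment_crossings(a, b, grid)
        tt = ta + mids * (tb - ta)
        keep = np.ones(len(pix), dtype=bool)
        keep[1:] = np.any(pix[1:] != pix[:-1], axis=1)
        if last_pix is not None and len(pix) and np.array_equal(pix[0], last_pix):
            keep[0] = False
        pix, tt = pix[keep], tt[keep]
        if len(pix) == 0:
            continue
        out_pix.append(pix)
        out_t.append(tt)
        out_v.append(np.column_stack([np.full(len(pix), svz), np.full(len(pix), svx)]))
        last_pix = pix[-1]
    if not out_pix:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in RASTER_COLUMNS[1:]})
    pix = np.vstack(out_pix)
    v = np.vstack(out_v)
    return pd.DataFrame(
        {
            "iz": pix[:, 0],
            "ix": pix[:, 1],
            "t_s": np.concatenate(out_t),
            "vz_mm_s": v[:, 0],
            "vx_mm_s": v[:, 1],
            "speed_mm_s": np.hypot(v[:, 0], v[:, 1]),
        }
    )


def rasterize_trackset(trackset: TrackSet, grid: Grid) -> pd.DataFrame:
    """Rasterize every track; adds a track_id column and drops off-grid pixels.

    Avoids per-track DataFrame construction: tracks are split on the
    sorted track_id column and the per-track results are concatenated as
    plain arrays.
    """
    df = trackset.df.sort_values(["track_id", "t_s"], kind="stable")
    tids = df["track_id"].to_numpy()
    cols = {
        c: df[c].to_numpy(float) for c in ("t_s", "z_um", "x_um", "vz_mm_s", "vx_mm_s")
    }
    bounds = np.flatnonzero(np.diff(tids)) + 1
    starts = np.concatenate([[0], bounds])
    stops = np.concatenate([bounds, [len(df)]])

    out_tid, out_pix, out_t, out_vz, out_vx = [], [], [], [], []
    for a, b in zip(starts, stops):
        tid = tids[a]
        pos = np.column_stack([cols["z_um"][a:b], cols["x_um"][a:b]])
        t = cols["t_s"][a:b]
        vz = cols["vz_mm_s"][a:b]
        vx = cols["vx_mm_s"][a:b]
        last_pix = None
        for k in range(len(pos) - 1):
            pix, mids = _segment_crossings(pos[k], pos[k + 1], grid)
            keep = np.ones(len(pix), dtype=bool)
            keep[1:] = np.any(pix[1:] != pix[:-1], axis=1)
            if last_pix is not None and len(pix) and np.array_equal(pix[0], last_pix):
                keep[0] = False
            pix = pix[keep]
            if len(pix) == 0:
                continue
            out_pix.append(pix)
            out_t.append(t[k] + mids[keep] * (t[k + 1] - t[k]))
            out_tid.append(np.full(len(pix), tid))
            out_vz.append(np.full(len(pix), vz[k]))
            out_vx.append(np.full(len(pix), vx[k]))
            last_pix = pix[-1]
    if not out_pix:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in RASTER_COLUMNS})
    pix = np.vstack(out_pix)
    vz = np.concatenate(out_vz)
    vx = np.concatenate(out_vx)
    out = pd.DataFrame(
        {
            "track_id": np.concatenate(out_tid),
            "iz": pix[:, 0],
            "ix": pix[:, 1],
            "t_s": np.concatenate(out_t),
            "vz_mm_s": vz,
            "vx_mm_s": vx,
            "speed_mm_s": np.hypot(vz, vx),
        }
    )
    ok = (out["iz"] >= 0) & (out["iz"] < grid.nz) & (out["ix"] >= 0) & (out["ix"] < grid.nx)
    return out.loc[ok].reset_index(drop=True)
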