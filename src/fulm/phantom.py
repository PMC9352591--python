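"""Synthetic vascular phantom: geometry, microbubble kinetics and rendering.

The phantom emulates what a coronal ultrafast acquisition of a continuously
injected contrast agent sees: a small set of vessel segments (pial surface
vessels, descending penetrating arterioles, ascending venules and
capillary-scale intraparenchymal branches) through which point-scatterer
microbubbles advect. Stimulus-locked functional hyperemia is modelled as a
multiplicative modulation of microbubble arrival rate (flux), advection
speed and effective lumen diameter inside segments flagged as activated.

Ground truth (every bubble position at every frame time, with its velocity
and parent segment) is retained so that downstream detection, tracking and
functional analysis can be scored exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clutter import FrameBlock
from .grids import Grid

COMPARTMENTS = ("pial", "penetrating_arteriole", "venule", "intraparenchymal")

#: net descent (µm) below which a segment is considered horizontal (pial)
_PIAL_DZ_TOL_UM = 1e-6


@dataclass(frozen=True)
class StimulusProtocol:
    """Repeated rest / stimulation / rest pattern.

    The default 30 s rest, 30 s stimulation, 10 s rest repeated 20 times
    gives a 70-s pattern and a 1400-s acquisition. ``boxcar`` is the 0/1
    stimulation signal A(t); its integral over the full acquisition equals
    ``stim * n_patterns``.
    """

    rest_pre: float = 30.0
    stim: float = 30.0
    rest_post: float = 10.0
    n_patterns: int = 20

    def __post_init__(self) -> None:
        if min(self.rest_pre, self.stim, self.rest_post) <= 0:
            raise ValueError("all protocol durations must be positive")
        if self.n_patterns < 1:
            raise ValueError("n_patterns must be >= 1")

    @property
    def pattern_t(self) -> float:
        return self.rest_pre + self.stim + self.rest_post

    @property
    def acq_t(self) -> float:
        return self.pattern_t * self.n_patterns

    @property
    def stim_window(self) -> tuple[float, float]:
        """Pattern-phase interval [on, off) of the stimulus."""
        return (self.rest_pre, self.rest_pre + self.stim)

    def phase(self, t) -> np.ndarray:
        return np.mod(np.asarray(t, dtype=float), self.pattern_t)

    def boxcar(self, t) -> np.ndarray:
        """A(t): 1 during stimulation, 0 at rest."""
        p = self.phase(t)
        on, off = self.stim_window
        return ((p >= on) & (p < off)).astype(float)

    def modulation(self, t, ramp: float = 2.0) -> np.ndarray:
        """Trapezoid-smoothed A(t): linear rise over ``ramp`` seconds from
        stimulus onset and linear fall over ``ramp`` seconds after offset.

        The integral per pattern equals the stimulus duration, so closed-form
        mean-rate expectations hold exactly.
        """
        if ramp < 0:
            raise ValueError("ramp must be non-negative")
        p = self.phase(t)
        on, off = self.stim_window
        if ramp == 0:
            return self.boxcar(t)
        if off + ramp > self.pattern_t:
            raise ValueError("ramp extends past the end of the pattern")
        rise = (p - on) / ramp
        fall = (off + ramp - p) / ramp
        return np.clip(np.minimum(rise, fall), 0.0, 1.0)


@dataclass(frozen=True)
class HemoModulation:
    """Multiplicative peak factors applied in activated segments during
    stimulation: microbubble arrival rate (flux_gain), advection speed
    (speed_gain) and lumen diameter (diameter_gain). Gains of 1 disable the
    response; the response shape is the protocol trapezoid with ``ramp``
    seconds of rise/fall."""

    flux_gain: float = 1.0
    speed_gain: float = 1.0
    diameter_gain: float = 1.0
    ramp: float = 2.0

    def __post_init__(self) -> None:
        if min(self.flux_gain, self.speed_gain, self.diameter_gain) < 0:
            raise ValueError("gains must be non-negative")


@dataclass
class Segment:
    """One vessel segment: a centreline polyline with uniform radius,
    baseline speed and microbubble arrival rate."""

    segment_id: int
    points_um: np.ndarray  # (N, 2) columns (z, x)
    radius_um: float
    speed_mm_s: float
    rate_mb_s: float
    compartment: str
    activated: bool = False

    def __post_init__(self) -> None:
        self.points_um = np.asarray(self.points_um, dtype=float)
        if self.points_um.ndim != 2 or self.points_um.shape[1] != 2 or len(self.points_um) < 2:
            raise ValueError("points_um must be an (N>=2, 2) array of (z, x)")
        if self.radius_um <= 0:
            raise ValueError("radius must be positive")
        if self.speed_mm_s < 0:
            raise ValueError("speed must be non-negative")
        if self.rate_mb_s < 0:
            raise ValueError("arrival rate must be non-negative")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        steps = np.diff(self.points_um, axis=0)
        seglen = np.hypot(steps[:, 0], steps[:, 1])
        if np.any(seglen <= 0):
            raise ValueError("zero-length segment in centreline polyline")
        self._arclen = np.concatenate([[0.0], np.cumsum(seglen)])

    @property
    def length_um(self) -> float:
        return float(self._arclen[-1])

    @property
    def net_dz_um(self) -> float:
        return float(self.points_um[-1, 0] - self.points_um[0, 0])

    def point_at(self, s) -> np.ndarray:
        """Centreline position(s) at arc length s (µm), shape (n, 2)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        z = np.interp(s, self._arclen, self.points_um[:, 0])
        x = np.interp(s, self._arclen, self.points_um[:, 1])
        return np.column_stack([z, x])

    def tangent_at(self, s) -> np.ndarray:
        """Unit tangent(s) (dz, dx) at arc length s."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        idx = np.clip(np.searchsorted(self._arclen, s, side="right") - 1, 0, len(self._arclen) - 2)
        steps = np.diff(self.points_um, axis=0)
        t = steps[idx]
        return t / np.linalg.norm(t, axis=1, keepdims=True)


@dataclass
class VascularPhantom:
    segments: list[Segment]

    def __post_init__(self) -> None:
        ids = [s.segment_id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise ValueError("segment ids must be unique")

    def __iter__(self):
        return iter(self.segments)

    def get(self, segment_id: int) -> Segment:
        for s in self.segments:
            if s.segment_id == segment_id:
                return s
        raise KeyError(segment_id)

    @property
    def activated_ids(self) -> list[int]:
        return [s.segment_id for s in self.segments if s.activated]


def _classify(points: np.ndarray, radius_um: float) -> str:
    dz = points[-1, 0] - points[0, 0]
    if abs(dz) <= _PIAL_DZ_TOL_UM:
        return "pial"
    if radius_um < 8.0:
        return "intraparenchymal"
    return "penetrating_arteriole" if dz > 0 else "venule"


def build_phantom(config: list[dict], seed: int = 0) -> VascularPhantom:
    """Build a phantom from a list of segment specifications.

    Each spec is a dict with keys ``points_um`` (list of (z, x) vertices),
    ``radius_um``, ``speed_mm_s``, ``rate_mb_s`` and optionally
    ``activated`` (default False) and ``compartment``. If the compartment
    is omitted it is classified from the flow direction: descending
    centrelines (z increases along flow) are penetrating arterioles,
    ascending ones venules, horizontal ones pial; small radii (< 8 µm)
    are intraparenchymal. Explicit arteriole/venule labels are validated
    against the flow direction. ``seed`` is accepted for API stability
    (future randomized branching); construction is deterministic.
    """
    if not config:
        raise ValueError("config must list at least one segment")
    del seed  # construction is currently fully deterministic
    segments = []
    for i, spec in enumerate(config):
        points = np.asarray(spec["points_um"], dtype=float)
        radius = float(spec["radius_um"])
        comp = spec.get("compartment")
        if comp is None:
            comp = _classify(points, radius)
        else:
            dz = points[-1, 0] - points[0, 0]
            if comp == "penetrating_arteriole" and dz <= 0:
                raise ValueError("arteriole segments must have descending flow (Vz > 0)")
            if comp == "venule" and dz >= 0:
                raise ValueError("venule segments must have ascending flow (Vz < 0)")
        segments.append(
            Segment(
                segment_id=int(spec.get("segment_id", i)),
                points_um=points,
                radius_um=radius,
                speed_mm_s=float(spec["speed_mm_s"]),
                rate_mb_s=float(spec["rate_mb_s"]),
                compartment=comp,
                activated=bool(spec.get("activated", False)),
            )
        )
    return VascularPhantom(segments)


TRACK_COLUMNS = ["track_id", "t_s", "z_um", "x_um", "vz_mm_s", "vx_mm_s", "segment_id"]


@dataclass
class GroundTruth:
    """Frame-sampled true microbubble trajectories plus provenance.

    ``tracks`` is a DataFrame with columns ``track_id, t_s, z_um, x_um,
    vz_mm_s, vx_mm_s, segment_id`` sampled on the global frame clock; every
    rendered echo corresponds to exactly one of its rows.
    """

    tracks: pd.DataFrame
    phantom: VascularPhantom
    protocol: StimulusProtocol
    modulation: HemoModulation
    frame_rate: float
    duration: float

    def to_trackset(self):
        """View the true trajectories as a tracking.TrackSet."""
        from .tracking import TrackSet

        df = self.tracks.copy()
        df["frame"] = np.round(df["t_s"].to_numpy() * self.frame_rate).astype(np.int64)
        df["speed_mm_s"] = np.hypot(df["vz_mm_s"], df["vx_mm_s"])
        return TrackSet(df=df, frame_rate=self.frame_rate, params={"source": "ground_truth"})

    def segment_pixel_mask(self, grid: Grid, segment_ids=None, dilate_radius: bool = True):
        """Boolean mask of super-grid pixels covered by the listed segments
        (centreline dilated by the segment radius when ``dilate_radius``)."""
        mask = np.zeros(grid.shape, dtype=bool)
        step = 0.5 * min(grid.pitch_z_um, grid.pitch_x_um)
        for seg in self.phantom:
            if segment_ids is not None and seg.segment_id not in segment_ids:
                continue
            s = np.arange(0.0, seg.length_um + step, step)
            pts = seg.point_at(s)
            if dilate_radius and seg.radius_um > 0:
                tan = seg.tangent_at(s)
                normal = np.column_stack([-tan[:, 1], tan[:, 0]])
                offs = np.linspace(-seg.radius_um, seg.radius_um, max(3, int(2 * seg.radius_um / step)))
                pts = (pts[:, None, :] + offs[None, :, None] * normal[:, None, :]).reshape(-1, 2)
            ok = grid.contains(pts[:, 0], pts[:, 1])
            iz, ix = grid.pos_to_index(pts[ok, 0], pts[ok, 1])
            mask[iz, ix] = True
        return mask

    def activated_pixel_mask(self, grid: Grid):
        return self.segment_pixel_mask(grid, segment_ids=set(self.phantom.activated_ids))


def simulate_microbubbles(
    phantom: VascularPhantom,
    protocol: StimulusProtocol,
    modulation: HemoModulation,
    duration: float,
    seed: int = 0,
    frame_rate: float = 1000.0,
    poiseuille: bool = False,
) -> GroundTruth:
    """Simulate microbubble passages through the phantom.

    Arrivals per segment follow a Poisson process at rate
    ``rate * (1 + (flux_gain - 1) * m(t))`` where ``m`` is the trapezoid
    response (activated segments only; constant ``rate`` otherwise),
    realised by thinning. Each bubble advects along the centreline at the
    segment speed scaled by the instantaneous speed modulation, with a
    lateral offset drawn uniformly within ``radius * diameter modulation``
    (frozen at arrival so per-track speed stays exact). Positions are
    sampled on the global frame clock.
    """
    if duration < protocol.pattern_t:
        raise ValueError("duration must cover at least one stimulation pattern")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration * frame_rate))
    t_grid = np.arange(n_frames + 1) / frame_rate
    any_modulated = any(s.activated for s in phantom) and (
        modulation.flux_gain != 1.0
        or modulation.speed_gain != 1.0
        or modulation.diameter_gain != 1.0
    )
    m_grid = (
        protocol.modulation(t_grid, ramp=modulation.ramp)
        if any_modulated
        else np.zeros(n_frames + 1)
    )

    rows = []
    track_id = 0
    dt = 1.0 / frame_rate
    for seg in phantom:
        if seg.rate_mb_s < 0:
            raise ValueError("negative arrival rate")
        if seg.rate_mb_s == 0:
            continue
        fg = modulation.flux_gain if seg.activated else 1.0
        sg = modulation.speed_gain if seg.activated else 1.0
        dg = modulation.diameter_gain if seg.activated else 1.0

        # Poisson arrivals by thinning against the peak rate.
        rate_max = seg.rate_mb_s * max(1.0, fg)
        n_cand = rng.poisson(rate_max * duration)
        t_cand = np.sort(rng.uniform(0.0, duration, n_cand))
        if fg != 1.0:
            accept = rng.uniform(0.0, 1.0, n_cand) * rate_max <= seg.rate_mb_s * (
                1.0 + (fg - 1.0) * protocol.modulation(t_cand, ramp=modulation.ramp)
            )
            t_arr = t_cand[accept]
        else:
            accept = rng.uniform(0.0, 1.0, n_cand) * rate_max <= seg.rate_mb_s
            t_arr = t_cand[accept]

        # Cumulative centreline distance C(t) shared by all bubbles of the
        # segment: ds/dt = v0 * (1 + (sg-1) m(t)), integrated on the frame
        # grid (piecewise-constant speed per frame interval).
        v_um_s = 1000.0 * seg.speed_mm_s * (1.0 + (sg - 1.0) * m_grid)
        c_grid = np.concatenate([[0.0], np.cumsum(v_um_s[:-1] * dt)])

        offs = rng.uniform(-1.0, 1.0, len(t_arr))
        for t0, u in zip(t_arr, offs):
            k0 = int(np.ceil(t0 * frame_rate - 1e-9))
            if k0 > n_frames:
                continue
            c0 = np.interp(t0, t_grid, c_grid)
            vel_factor = 1.5 * (1.0 - u * u) if poiseuille else 1.0
            # distance travelled since arrival, at frame times
            s = (c_grid[k0:] - c0) * vel_factor
            k_end = k0 + int(np.searchsorted(s, seg.length_um, side="right"))
            if k_end <= k0:
                continue
            ks = np.arange(k0, min(k_end, n_frames + 1))
            s = s[: len(ks)]
            pos = seg.point_at(s)
            tan = seg.tangent_at(s)
            r_eff = seg.radius_um
            if dg != 1.0:
                r_eff *= 1.0 + (dg - 1.0) * float(
                    protocol.modulation(t0, ramp=modulation.ramp)
                )
            normal = np.column_stack([-tan[:, 1], tan[:, 0]])
            pos = pos + u * r_eff * normal
            v_mm = seg.speed_mm_s * (1.0 + (sg - 1.0) * m_grid[ks]) * vel_factor
            n = len(ks)
            rows.append(
                (
                    np.full(n, track_id, dtype=np.int64),
                    t_grid[ks],
                    pos[:, 0],
                    pos[:, 1],
                    v_mm * tan[:, 0],
                    v_mm * tan[:, 1],
                    np.full(n, seg.segment_id, dtype=np.int64),
                )
            )
            track_id += 1
    if rows:
        cat = [np.concatenate([r[j] for r in rows]) for j in range(7)]
        tracks = pd.DataFrame(dict(zip(TRACK_COLUMNS, cat)))
    else:
        tracks = pd.DataFrame({c: pd.Series(dtype=float) for c in TRACK_COLUMNS})
    return GroundTruth(
        tracks=tracks,
        phantom=phantom,
        protocol=protocol,
        modulation=modulation,
        frame_rate=frame_rate,
        duration=duration,
    )


def apply_motion(
    tracks: pd.DataFrame,
    drift_um_s: tuple[float, float] = (0.0, 0.0),
    pulsatile_um: float = 0.0,
    pulsatile_hz: float = 5.0,
) -> pd.DataFrame:
    """Shift microbubble positions by slow linear drift plus a pulsatile
    (cardiac-like) axial oscillation; returns a copy."""
    out = tracks.copy()
    t = out["t_s"].to_numpy()
    out["z_um"] = out["z_um"] + drift_um_s[0] * t + pulsatile_um * np.sin(2 * np.pi * pulsatile_hz * t)
    out["x_um"] = out["x_um"] + drift_um_s[1] * t
    return out


def render_frame_block(
    truth: GroundTruth,
    grid: Grid,
    psf_sigma_um: tuple[float, float] = (70.0, 70.0),
    clutter_rank: int = 0,
    clutter_amp: float = 20.0,
    noise_sigma: float = 0.0,
    drift_um_s: tuple[float, float] = (0.0, 0.0),
    pulsatile_um: float = 0.0,
    pulsatile_hz: float = 5.0,
    block_len: int = 400,
    amplitude: float = 1.0,
    t_range: tuple[float, float] | None = None,
    seed: int = 0,
) -> list[FrameBlock]:
    """Render ultrafast frame blocks from ground-truth bubble positions.

    Each bubble adds a Gaussian spot (the point-spread function of an
    isolated scatterer) at its possibly motion-shifted position; tissue
    clutter is a sum of ``clutter_rank`` fixed smooth spatial patterns with
    slowly varying temporal weights, plus additive white noise. Rendering is
    intended for block-scale durations (seconds), not whole acquisitions.
    """
    if psf_sigma_um[0] <= 0 or psf_sigma_um[1] <= 0:
        raise ValueError("psf_sigma must be positive")
    rng = np.random.default_rng(seed)
    fr = truth.frame_rate
    if t_range is None:
        t_range = (0.0, truth.duration)
    k_start = int(round(t_range[0] * fr))
    n_frames = int(round((t_range[1] - t_range[0]) * fr))
    if n_frames < 2:
        raise ValueError("t_range must cover at least two frames")

    frames = np.zeros((grid.nz, grid.nx, n_frames), dtype=float)
    moved = apply_motion(truth.tracks, drift_um_s, pulsatile_um, pulsatile_hz)
    kf = np.round(moved["t_s"].to_numpy() * fr).astype(np.int64) - k_start
    sel = (kf >= 0) & (kf < n_frames)
    zs = moved["z_um"].to_numpy()[sel]
    xs = moved["x_um"].to_numpy()[sel]
    kf = kf[sel]

    sz, sx = psf_sigma_um
    wz = int(np.ceil(4 * sz / grid.pitch_z_um))
    wx = int(np.ceil(4 * sx / grid.pitch_x_um))
    zc = (np.arange(grid.nz) + 0.5) * grid.pitch_z_um
    xc = (np.arange(grid.nx) + 0.5) * grid.pitch_x_um
    for z, x, k in zip(zs, xs, kf):
        iz, ix = grid.pos_to_index(z, x)
        z0, z1 = max(0, iz - wz), min(grid.nz, iz + wz + 1)
        x0, x1 = max(0, ix - wx), min(grid.nx, ix + wx + 1)
        if z0 >= z1 or x0 >= x1:
            continue
        gz = np.exp(-0.5 * ((zc[z0:z1] - z) / sz) ** 2)
        gx = np.exp(-0.5 * ((xc[x0:x1] - x) / sx) ** 2)
        frames[z0:z1, x0:x1, k] += amplitude * np.outer(gz, gx)

    if clutter_rank > 0:
        from scipy import ndimage

        tt = (np.arange(n_frames) + k_start) / fr
        for r in range(clutter_rank):
            pattern = ndimage.gaussian_filter(rng.normal(size=grid.shape), sigma=3.0)
            pattern /= np.abs(pattern).max()
            f_hz = 0.2 + 0.4 * r
            weights = 1.0 + 0.3 * np.sin(2 * np.pi * f_hz * tt + rng.uniform(0, 2 * np.pi))
            frames += clutter_amp * pattern[:, :, None] * weights[None, None, :]
    if noise_sigma > 0:
        frames += rng.normal(scale=noise_sigma, size=frames.shape)

    blocks = []
    for start in range(0, n_frames, block_len):
        stop = min(start + block_len, n_frames)
        if stop - start < 2:
            break
        blocks.append(
            FrameBlock(
                frames=frames[:, :, start:stop],
                frame_rate=fr,
                pitch_um=(grid.pitch_z_um, grid.pitch_x_um),
                t0=(k_start + start) / fr,
            )
        )
    return blocks
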