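"""Static and dynamic super-resolved microbubble maps.

A static map counts, per super-resolved pixel, the bubble-path traversals
during an accumulation period, with the mean traversal speed alongside.
Dynamic imaging rasterizes the same data into a sliding-window movie
M(x, z, t) (window W_t, step Step_t; Nt = Acq_t / Step_t maps) and, for a
repeated stimulation protocol, a pattern-averaged movie that sums
equivalent phase points across the Nb_pattern repetitions and divides by
the window length to yield a microbubble flux MB_F in MB/s
(Nt_s = Pattern_t / Step_t phase points). Slow positional drift is
corrected by translation-only registration of chunked count maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .grids import Grid
from .phantom import StimulusProtocol
from .tracking import TrackSet, rasterize_trackset

#: default sliding-window length (s) and step (s)
W_T = 5.0
STEP_T = 1.0
#: pixels with fewer total detections are flagged invalid for analysis
MIN_PIXEL_COUNT = 5


@dataclass
class MapSet:
    """Accumulated maps: traversal count, mean speed and mean velocity
    components per pixel; ``valid_mask`` flags pixels with at least
    ``MIN_PIXEL_COUNT`` detections."""

    count: np.ndarray
    velocity: np.ndarray
    vz: np.ndarray
    vx: np.ndarray
    valid_mask: np.ndarray
    grid: Grid


@dataclass
class UlmMovie:
    """Sliding-window movie: counts (Nz, Nx, Nt) and mean speed, with the
    window centres on ``t_centers`` (t_k = k * Step_t)."""

    counts: np.ndarray
    velocity: np.ndarray
    w_t: float
    step_t: float
    grid: Grid
    t_centers: np.ndarray

    @property
    def n_t(self) -> int:
        return self.counts.shape[2]


@dataclass
class PatternMovie:
    """Pattern-averaged movie over the Nt_s = Pattern_t / Step_t phase
    points of the stimulation pattern.

    ``counts`` holds the raw pattern-summed counts (exactly conserved
    against the sliding movie); ``flux`` is the unbiased MB/s estimate
    (counts / W_t, rescaled where acquisition-edge windows are truncated).
    """

    flux: np.ndarray
    velocity: np.ndarray
    w_t: float
    step_t: float
    grid: Grid
    protocol: StimulusProtocol
    phases: np.ndarray
    counts: np.ndarray | None = None

    @property
    def n_t(self) -> int:
        return self.flux.shape[2]


def n_windows(acq_t: float, step_t: float = STEP_T) -> int:
    """Nt = Acq_t / Step_t, the number of sliding-window maps."""
    return int(round(acq_t / step_t))


def n_pattern_windows(pattern_t: float, step_t: float = STEP_T) -> int:
    """Nt_s = Pattern_t / Step_t, the pattern-phase points."""
    return int(round(pattern_t / step_t))


def _accumulate(raster: pd.DataFrame, grid: Grid):
    count = np.zeros(grid.shape)
    sumv = np.zeros(grid.shape)
    sumvz = np.zeros(grid.shape)
    sumvx = np.zeros(grid.shape)
    if len(raster):
        iz = raster["iz"].to_numpy(np.int64)
        ix = raster["ix"].to_numpy(np.int64)
        np.add.at(count, (iz, ix), 1.0)
        np.add.at(sumv, (iz, ix), raster["speed_mm_s"].to_numpy(float))
        np.add.at(sumvz, (iz, ix), raster["vz_mm_s"].to_numpy(float))
        np.add.at(sumvx, (iz, ix), raster["vx_mm_s"].to_numpy(float))
    return count, sumv, sumvz, sumvx


def accumulate_maps(
    raster: pd.DataFrame,
    grid: Grid,
    t_range: tuple[float, float] | None = None,
    min_count: int = MIN_PIXEL_COUNT,
) -> MapSet:
    """Count and mean-velocity maps over a half-open time range.

    The count is the number of distinct track traversals per pixel; the
    velocity maps are means over those traversals (zero where no data).
    """
    if t_range is not None:
        if t_range[1] <= t_range[0]:
            raise ValueError("empty t_range")
        sel = (raster["t_s"] >= t_range[0]) & (raster["t_s"] < t_range[1])
        raster = raster.loc[sel]
    count, sumv, sumvz, sumvx = _accumulate(raster, grid)
    with np.errstate(invalid="ignore", divide="ignore"):
        vel = np.where(count > 0, sumv / np.maximum(count, 1), 0.0)
        vz = np.where(count > 0, sumvz / np.maximum(count, 1), 0.0)
        vx = np.where(count > 0, sumvx / np.maximum(count, 1), 0.0)
    return MapSet(count=count, velocity=vel, vz=vz, vx=vx, valid_mask=count >= min_count, grid=grid)


def build_sliding_movie(
    raster: pd.DataFrame,
    grid: Grid,
    acq_t: float,
    w_t: float = W_T,
    step_t: float = STEP_T,
) -> UlmMovie:
    """Rasterize detections into the sliding-window movie M(x, z, t).

    Window k is the half-open interval [t_k - W_t/2, t_k + W_t/2) centred
    on t_k = k * Step_t, using each pixel traversal's interpolated
    timestamp; windows extending past the acquisition are truncated.
    """
    if w_t <= 0:
        raise ValueError("window length must be positive")
    if w_t < step_t:
        warnings.warn("window shorter than step: some detections fall in no window")
    nt = n_windows(acq_t, step_t)
    counts = np.zeros((grid.nz, grid.nx, nt), dtype=np.float32)
    vel = np.zeros_like(counts)
    order = np.argsort(raster["t_s"].to_numpy(), kind="stable")
    t = raster["t_s"].to_numpy()[order]
    iz = raster["iz"].to_numpy(np.int64)[order]
    ix = raster["ix"].to_numpy(np.int64)[order]
    sp = raster["speed_mm_s"].to_numpy(float)[order]
    centers = np.arange(nt) * step_t
    for k, tk in enumerate(centers):
        a, b = np.searchsorted(t, [tk - w_t / 2, tk + w_t / 2])
        if b <= a:
            continue
        c = np.zeros(grid.shape, dtype=np.float32)
        s = np.zeros(grid.shape, dtype=np.float32)
        np.add.at(c, (iz[a:b], ix[a:b]), 1.0)
        np.add.at(s, (iz[a:b], ix[a:b]), sp[a:b].astype(np.float32))
        counts[:, :, k] = c
        with np.errstate(invalid="ignore", divide="ignore"):
            vel[:, :, k] = np.where(c > 0, s / np.maximum(c, 1), 0.0)
    return UlmMovie(counts=counts, velocity=vel, w_t=w_t, step_t=step_t, grid=grid, t_centers=centers)


def _phase_scale(protocol: StimulusProtocol, nts: int, w_t: float, step_t: float) -> np.ndarray:
    """Per-phase correction for windows truncated at the acquisition edges.

    The windows of the very first and last pattern extend past [0, Acq_t]
    and are truncated; without compensation every pixel's phase profile
    dips at the pattern edges, which correlates spuriously with any
    mid-pattern stimulus. The scale restores an unbiased flux estimate:
    n_patterns * W_t / (effective accumulation time of the phase).
    """
    acq = protocol.acq_t
    eff = np.zeros(nts)
    for k in range(nts):
        for i in range(protocol.n_patterns):
            tk = k * step_t + i * protocol.pattern_t
            eff[k] += max(0.0, min(tk + w_t / 2, acq) - max(tk - w_t / 2, 0.0))
    with np.errstate(divide="ignore"):
        return np.where(eff > 0, protocol.n_patterns * w_t / eff, 0.0)


def pattern_average(movie: UlmMovie, protocol: StimulusProtocol) -> PatternMovie:
    """Sum equivalent phase points across pattern repetitions.

    MB_F(x, z, t) = (1/W_t) * sum_i MB(x, z, t + i * Pattern_t), with the
    phases whose windows are truncated at the acquisition edges rescaled
    to unbiased flux; the speed is the pooled mean of all bubbles detected
    in the contributing windows (count-weighted, not a mean of
    per-repetition means). Requires Acq_t = Nb_pattern * Pattern_t on the
    movie's step grid.
    """
    nts = n_pattern_windows(protocol.pattern_t, movie.step_t)
    if abs(nts * movie.step_t - protocol.pattern_t) > 1e-9:
        raise ValueError("step_t must divide the pattern duration")
    if movie.n_t != protocol.n_patterns * nts:
        raise ValueError(
            f"movie has {movie.n_t} windows, protocol implies {protocol.n_patterns * nts}"
        )
    nz, nx, _ = movie.counts.shape
    c = movie.counts.reshape(nz, nx, protocol.n_patterns, nts)
    sv = (movie.counts * movie.velocity).reshape(nz, nx, protocol.n_patterns, nts)
    csum = c.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        vel = np.where(csum > 0, sv.sum(axis=2) / np.maximum(csum, 1), 0.0)
    scale = _phase_scale(protocol, nts, movie.w_t, movie.step_t)
    return PatternMovie(
        flux=csum / movie.w_t * scale[None, None, :],
        velocity=vel,
        w_t=movie.w_t,
        step_t=movie.step_t,
        grid=movie.grid,
        protocol=protocol,
        phases=np.arange(nts) * movie.step_t,
        counts=csum,
    )


def pattern_average_streaming(
    raster: pd.DataFrame,
    grid: Grid,
    protocol: StimulusProtocol,
    w_t: float = W_T,
    step_t: float = STEP_T,
) -> PatternMovie:
    """Pattern-averaged movie accumulated window-by-window.

    Identical to ``pattern_average(build_sliding_movie(...), protocol)``
    but never materializes the full (Nz, Nx, Nt) movie: each of the
    Nt = Acq_t/Step_t absolute-time windows is folded directly into its
    pattern phase. Useful for long acquisitions.
    """
    nts = n_pattern_windows(protocol.pattern_t, step_t)
    if abs(nts * step_t - protocol.pattern_t) > 1e-9:
        raise ValueError("step_t must divide the pattern duration")
    nt = n_windows(protocol.acq_t, step_t)
    csum = np.zeros((grid.nz, grid.nx, nts))
    svsum = np.zeros_like(csum)
    order = np.argsort(raster["t_s"].to_numpy(), kind="stable")
    t = raster["t_s"].to_numpy()[order]
    iz = raster["iz"].to_numpy(np.int64)[order]
    ix = raster["ix"].to_numpy(np.int64)[order]
    sp = raster["speed_mm_s"].to_numpy(float)[order]
    for k in range(nt):
        tk = k * step_t
        a, b = np.searchsorted(t, [tk - w_t / 2, tk + w_t / 2])
        if b <= a:
            continue
        phase_k = k % nts
        np.add.at(csum[:, :, phase_k], (iz[a:b], ix[a:b]), 1.0)
        np.add.at(svsum[:, :, phase_k], (iz[a:b], ix[a:b]), sp[a:b])
    with np.errstate(invalid="ignore", divide="ignore"):
        vel = np.where(csum > 0, svsum / np.maximum(csum, 1), 0.0)
    scale = _phase_scale(protocol, nts, w_t, step_t)
    return PatternMovie(
        flux=csum / w_t * scale[None, None, :],
        velocity=vel,
        w_t=w_t,
        step_t=step_t,
        grid=grid,
        protocol=protocol,
        phases=np.arange(nts) * step_t,
        counts=csum,
    )


def pattern_movie_from_tracks(
    trackset: TrackSet,
    grid: Grid,
    protocol: StimulusProtocol,
    w_t: float = W_T,
    step_t: float = STEP_T,
) -> PatternMovie:
    """Convenience: rasterize tracks and pattern-average (streaming path)."""
    raster = rasterize_trackset(trackset, grid)
    return pattern_average_streaming(raster, grid, protocol, w_t=w_t, step_t=step_t)


def estimate_and_apply_drift(
    trackset: TrackSet,
    grid: Grid,
    chunk_s: float = 10.0,
    smooth_px: float = 2.0,
    upsample: int = 8,
) -> tuple[TrackSet, pd.DataFrame]:
    """Estimate slow positional drift and subtract it from all coordinates.

    Count maps are built on ``chunk_s`` chunks (10-s by default) of the
    acquisition, lightly smoothed (the super-resolved maps are sparse) and
    registered to the first chunk with translation-only intensity
    registration (phase cross-correlation). The per-chunk shift is
    subtracted from every bubble position in that chunk. Returns the
    corrected TrackSet and a table (chunk, t0_s, dz_um, dx_um).
    """
    df = trackset.df
    t = df["t_s"].to_numpy()
    n_chunks = int(np.ceil((t.max() + 1e-9) / chunk_s)) if len(df) else 0
    if n_chunks < 2:
        raise ValueError("drift estimation needs at least 2 chunks")
    raster = rasterize_trackset(trackset, grid)

    def chunk_map(k):
        sel = (raster["t_s"] >= k * chunk_s) & (raster["t_s"] < (k + 1) * chunk_s)
        m = np.zeros(grid.shape)
        sub = raster.loc[sel]
        if len(sub):
            np.add.at(m, (sub["iz"].to_numpy(np.int64), sub["ix"].to_numpy(np.int64)), 1.0)
        return ndimage.gaussian_filter(m, smooth_px) if smooth_px > 0 else m

    ref = chunk_map(0)
    rows = [(0, 0.0, 0.0, 0.0)]
    shifts = np.zeros((n_chunks, 2))
    for k in range(1, n_chunks):
        mov = chunk_map(k)
        if ref.sum() == 0 or mov.sum() == 0:
            warnings.warn(f"registration failed for chunk {k} (no overlap); zero shift")
            sh = np.zeros(2)
        else:
            sh, _, _ = phase_cross_correlation(ref, mov, upsample_factor=upsample)
            # shift registers `mov` onto `ref`: mov was displaced by -sh
        dz_um = -float(sh[0]) * grid.pitch_z_um
        dx_um = -float(sh[1]) * grid.pitch_x_um
        shifts[k] = (dz_um, dx_um)
        rows.append((k, k * chunk_s, dz_um, dx_um))

    out = df.copy()
    ck = np.minimum((t / chunk_s).astype(int), n_chunks - 1)
    out["z_um"] = out["z_um"] - shifts[ck, 0]
    out["x_um"] = out["x_um"] - shifts[ck, 1]
    corrected = replace(trackset, df=out)
    return corrected, pd.DataFrame(rows, columns=["chunk", "t0_s", "dz_um", "dx_um"])


def split_rest_stim_maps(
    raster: pd.DataFrame,
    grid: Grid,
    protocol: StimulusProtocol,
    min_count: int = MIN_PIXEL_COUNT,
) -> tuple[MapSet, MapSet]:
    """Count/velocity map pairs for the baseline and stimulation subsets.

    Baseline is pattern phase [0, rest_pre), stimulation
    [rest_pre, rest_pre + stim); the post-stimulus rest is excluded from
    both subsets.
    """
    phase = protocol.phase(raster["t_s"].to_numpy())
    on, off = protocol.stim_window
    rest = raster.loc[(phase >= 0) & (phase < on)]
    stim = raster.loc[(phase >= on) & (phase < off)]
    return (
        accumulate_maps(rest, grid, min_count=min_count),
        accumulate_maps(stim, grid, min_count=min_count),
    )
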