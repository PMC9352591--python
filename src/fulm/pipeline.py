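"""Reproducible end-to-end pipeline over the processing stages.

``run_pipeline`` executes simulate -> (render -> filter -> localize ->
track, when rendering is enabled; otherwise the ground-truth tracks feed
the analysis directly) -> maps -> functional activation, writing every
artifact with provenance (config hash, package versions, seed) to a JSON-
lines log. All randomness flows from the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .clutter import svd_clutter_filter
from .config import PipelineConfig, default_two_vessel_segments
from .functional import correlation_map, detect_stim_mode, variation_map
from .grids import Grid
from .localize import localize_block
from .maps import accumulate_maps, build_sliding_movie, estimate_and_apply_drift, pattern_average
from .phantom import (
    HemoModulation,
    StimulusProtocol,
    build_phantom,
    render_frame_block,
    simulate_microbubbles,
)
from .tracking import assemble_and_filter, rasterize_trackset


def _config_hash(config: PipelineConfig) -> str:
    blob = yaml.safe_dump(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class _StageLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def write(self, stage: str, **fields) -> None:
        rec = {"stage": stage, "time_s": round(time.time(), 3), **fields}
        with open(self.path, "a") as f:
            f.write(json.dumps(rec) + "\n")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run all stages; returns a dict of in-memory results.

    Artifacts written under ``outdir``: tracks.csv, count/velocity maps
    (TIFF), the pattern movie (HDF5), activation maps and a pipeline.log
    (JSON lines). A stage failure raises a stage-named RuntimeError;
    artifacts of completed stages are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _StageLog(outdir / "pipeline.log")
    log.write(
        "provenance",
        config_hash=_config_hash(config),
        seed=config.seed,
        numpy=np.__version__,
        pandas=pd.__version__,
    )
    results: dict = {}
    stage = "simulate"
    try:
        protocol = StimulusProtocol(
            rest_pre=config.protocol.rest_pre,
            stim=config.protocol.stim,
            rest_post=config.protocol.rest_post,
            n_patterns=config.protocol.n_patterns,
        )
        seg_cfg = [s.model_dump(exclude_none=True) for s in config.simulate.segments]
        if not seg_cfg:
            seg_cfg = default_two_vessel_segments(config.simulate.grid_nz, config.simulate.grid_nx)
        phantom = build_phantom(seg_cfg, seed=config.seed)
        modulation = HemoModulation(
            flux_gain=config.simulate.flux_gain,
            speed_gain=config.simulate.speed_gain,
            diameter_gain=config.simulate.diameter_gain,
            ramp=config.simulate.ramp_s,
        )
        truth = simulate_microbubbles(
            phantom,
            protocol,
            modulation,
            duration=protocol.acq_t,
            seed=config.seed,
            frame_rate=config.simulate.frame_rate_hz,
        )
        results["truth"] = truth
        log.write(stage, n_tracks=int(truth.tracks["track_id"].nunique()))

        coarse = Grid(
            nz=config.simulate.grid_nz,
            nx=config.simulate.grid_nx,
            pitch_z_um=100.0,
            pitch_x_um=110.0,
        )
        grid = coarse.super_grid(config.maps.sr_factor)

        if config.simulate.render:
            stage = "render"
            blocks = render_frame_block(
                truth,
                coarse,
                clutter_rank=config.simulate.clutter_rank,
                clutter_amp=config.simulate.clutter_amp,
                noise_sigma=config.simulate.noise_sigma,
                drift_um_s=tuple(config.simulate.drift_um_s),
                t_range=tuple(config.simulate.render_t_range_s),
                seed=config.seed + 1,
            )
            log.write(stage, n_blocks=len(blocks))

            stage = "filter"
            filtered = [svd_clutter_filter(b, config.filter.n_discard) for b in blocks]
            log.write(stage, n_discard=config.filter.n_discard)

            stage = "localize"
            detections = pd.concat(
                [
                    localize_block(
                        b,
                        corr_threshold=config.localize.corr_threshold,
                        interp_factor=config.localize.interp_factor,
                        max_per_frame=config.localize.max_per_frame,
                        use_vesselness=config.localize.use_vesselness,
                    )
                    for b in filtered
                ],
                ignore_index=True,
            )
            fio.write_detections(outdir / "detections.csv", detections)
            log.write(stage, n_detections=len(detections))

            stage = "track"
            trackset = assemble_and_filter(
                detections,
                frame_rate=config.simulate.frame_rate_hz,
                max_speed_mm_s=config.track.max_speed_mm_s,
                min_len=config.track.min_len,
            )
            n_kept = len(trackset.df)
            frac = n_kept / max(len(detections), 1)
            log.write(stage, n_tracks=trackset.n_tracks, fraction_retained=round(frac, 4))
        else:
            stage = "track"
            trackset = truth.to_trackset()
            log.write(stage, n_tracks=trackset.n_tracks, source="ground_truth")
        results["trackset"] = trackset
        fio.write_tracks(outdir / "tracks.csv", trackset)

        if config.maps.drift_correction:
            stage = "drift"
            trackset, shifts = estimate_and_apply_drift(
                trackset, grid, chunk_s=config.maps.drift_chunk_s
            )
            shifts.to_csv(outdir / "drift_shifts.csv", index=False)
            log.write(stage, n_chunks=len(shifts))

        stage = "maps"
        raster = rasterize_trackset(trackset, grid)
        static = accumulate_maps(raster, grid, min_count=config.maps.min_pixel_count)
        fio.write_map_tiff(outdir / "mb_count.tif", static.count)
        fio.write_map_tiff(outdir / "velocity.tif", static.velocity)
        movie = build_sliding_movie(
            raster, grid, acq_t=protocol.acq_t, w_t=config.maps.w_t, step_t=config.maps.step_t
        )
        pm = pattern_average(movie, protocol)
        fio.write_movie(outdir / "pattern_movie.h5", movie, protocol)
        results.update(raster=raster, static_maps=static, movie=movie, pattern_movie=pm)
        log.write(stage, n_windows=movie.n_t, n_phases=pm.n_t)

        stage = "functional"
        a_t = protocol.boxcar(pm.phases)
        if config.functional.method == "correlation":
            flux = pm.flux.copy()
            flux[~static.valid_mask] = 0.0
            act = correlation_map(flux, a_t)
            results["activation_map"] = act
            results["i_stim"] = None
        else:
            valid_raster = raster.loc[
                static.valid_mask[raster["iz"].to_numpy(), raster["ix"].to_numpy()]
            ]
            pm_svd, svd, i_stim, rho = detect_stim_mode(
                valid_raster,
                grid,
                protocol,
                w_t=config.maps.w_t,
                step_t=config.maps.step_t,
                rho_min=config.functional.rho_min,
            )
            act = (
                variation_map(svd, pm_svd.phases, protocol.stim_window, (0.0, protocol.rest_pre))
                if i_stim is not None
                else np.zeros(grid.shape)
            )
            results["activation_map"] = act
            results["svd"] = svd
            results["i_stim"] = i_stim
            results["split_half_rho"] = rho
        fio.write_map_tiff(outdir / "activation.tif", act)
        log.write(stage, method=config.functional.method, i_stim=results.get("i_stim"))
    except Exception as e:  # noqa: BLE001 - halt with stage-named error
        log.write("error", failed_stage=stage, error=str(e))
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e
    return results
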