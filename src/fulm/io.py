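"""Readers and writers for the pipeline's exchange formats.

Frames travel as HDF5 (dataset ``/frames`` with metadata attributes) or
multi-page TIFF with a JSON sidecar; tracks and detections as CSV with
fixed column schemas; movies as HDF5 with ``/mb_count`` and ``/velocity``
datasets. All containers round-trip without loss.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .clutter import FrameBlock
from .grids import Grid
from .maps import UlmMovie
from .phantom import StimulusProtocol
from .tracking import TRACKSET_COLUMNS, TrackSet

TRACK_CSV_COLUMNS = ["track_id", "frame", "t_s", "z_um", "x_um", "vz_mm_s", "vx_mm_s"]
DETECTION_CSV_COLUMNS = ["t_s", "z_um", "x_um", "amp", "corr"]


def write_frames(path, block: FrameBlock) -> None:
    """Write a frame block to HDF5 (.h5) or TIFF + JSON sidecar (.tif)."""
    path = Path(path)
    meta = {
        "frame_rate_hz": block.frame_rate,
        "pitch_um_z": block.pitch_um[0],
        "pitch_um_x": block.pitch_um[1],
        "block_len": block.n_frames,
        "t0_s": block.t0,
    }
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=block.frames)
            for k, v in meta.items():
                f.attrs[k] = v
    elif path.suffix in (".tif", ".tiff"):
        if np.iscomplexobj(block.frames):
            raise ValueError("TIFF cannot store complex frames; use HDF5")
        tifffile.imwrite(path, np.moveaxis(block.frames, 2, 0).astype(np.float32))
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))
    else:
        raise ValueError(f"unsupported frame format: {path.suffix}")


def read_frames(path) -> FrameBlock:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        try:
            with h5py.File(path, "r") as f:
                frames = f["frames"][()]
                meta = dict(f.attrs)
        except OSError as e:
            raise OSError(f"corrupt or unreadable frame file {path}: {e}") from e
    elif path.suffix in (".tif", ".tiff"):
        try:
            frames = np.moveaxis(tifffile.imread(path), 0, 2)
        except (tifffile.TiffFileError, ValueError) as e:
            raise OSError(f"corrupt or unreadable frame file {path}: {e}") from e
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    else:
        raise ValueError(f"unsupported frame format: {path.suffix}")
    return FrameBlock(
        frames=frames,
        frame_rate=float(meta["frame_rate_hz"]),
        pitch_um=(float(meta["pitch_um_z"]), float(meta["pitch_um_x"])),
        t0=float(meta.get("t0_s", 0.0)),
    )


def write_tracks(path, trackset: TrackSet) -> None:
    cols = [c for c in TRACKSET_COLUMNS if c in trackset.df.columns]
    df = trackset.df[cols].copy()
    df.attrs = {}
    header = json.dumps({"frame_rate": trackset.frame_rate, "params": trackset.params})
    with open(path, "w") as f:
        f.write(f"# fulm-tracks {header}\n")
        df.to_csv(f, index=False, float_format="%.6f")


def read_tracks(path) -> TrackSet:
    path = Path(path)
    with open(path) as f:
        first = f.readline()
        meta = {"frame_rate": 1000.0, "params": {}}
        if first.startswith("# fulm-tracks"):
            meta = json.loads(first.split("# fulm-tracks", 1)[1])
            df = pd.read_csv(f)
        else:
            df = pd.read_csv(path)
    missing = [c for c in TRACK_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track CSV {path} is missing columns: {missing}")
    if "speed_mm_s" not in df.columns:
        df["speed_mm_s"] = np.hypot(df["vz_mm_s"], df["vx_mm_s"])
    return TrackSet(df=df, frame_rate=float(meta["frame_rate"]), params=dict(meta.get("params", {})))


def write_detections(path, detections: pd.DataFrame) -> None:
    detections[DETECTION_CSV_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def read_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in DETECTION_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"detection CSV {path} is missing columns: {missing}")
    return df


def write_movie(path, movie: UlmMovie, protocol: StimulusProtocol | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("mb_count", data=movie.counts, compression="gzip")
        f.create_dataset("velocity", data=movie.velocity, compression="gzip")
        f.attrs["w_t"] = movie.w_t
        f.attrs["step_t"] = movie.step_t
        f.attrs["pitch_um"] = (movie.grid.pitch_z_um, movie.grid.pitch_x_um)
        if protocol is not None:
            f.attrs["protocol"] = json.dumps(asdict(protocol))


def read_movie(path) -> tuple[UlmMovie, StimulusProtocol | None]:
    with h5py.File(path, "r") as f:
        counts = f["mb_count"][()]
        velocity = f["velocity"][()]
        w_t = float(f.attrs["w_t"])
        step_t = float(f.attrs["step_t"])
        pz, px = (float(v) for v in f.attrs["pitch_um"])
        proto = None
        if "protocol" in f.attrs:
            proto = StimulusProtocol(**json.loads(f.attrs["protocol"]))
        else:
            warnings.warn(f"movie {path} lacks a protocol attribute; reading without one")
    grid = Grid(nz=counts.shape[0], nx=counts.shape[1], pitch_z_um=pz, pitch_x_um=px)
    movie = UlmMovie(
        counts=counts,
        velocity=velocity,
        w_t=w_t,
        step_t=step_t,
        grid=grid,
        t_centers=np.arange(counts.shape[2]) * step_t,
    )
    return movie, proto


def write_map_tiff(path, image: np.ndarray) -> None:
    """Export a 2D map as 32-bit floating-point TIFF."""
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_map_tiff(path) -> np.ndarray:
    return tifffile.imread(path)
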