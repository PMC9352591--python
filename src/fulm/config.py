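"""Pipeline configuration: every stage parameter with its default.

Defaults mirror the standard acquisition settings: PSF-correlation
threshold 0.7, minimum track length 10 frames, 100 mm/s speed gate, 10
singular values discarded per contrast block (60 for Power Doppler),
5-s window with 1-s step, super-resolution factor 16 and a 5-detection
minimum per analysed pixel. Configs serialize to YAML and round-trip
without loss; unknown keys are rejected.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolConfig(_Strict):
    rest_pre: float = 30.0
    stim: float = 30.0
    rest_post: float = 10.0
    n_patterns: int = 20


class SegmentConfig(_Strict):
    points_um: list[list[float]]
    radius_um: float
    speed_mm_s: float
    rate_mb_s: float
    activated: bool = False
    compartment: str | None = None


class SimulateConfig(_Strict):
    segments: list[SegmentConfig] = Field(default_factory=list)
    flux_gain: float = 1.5
    speed_gain: float = 1.1
    diameter_gain: float = 1.1
    ramp_s: float = 2.0
    frame_rate_hz: float = 1000.0
    grid_nz: int = 16
    grid_nx: int = 16
    render: bool = False
    render_t_range_s: list[float] = Field(default_factory=lambda: [0.0, 2.0])
    clutter_rank: int = 3
    clutter_amp: float = 20.0
    noise_sigma: float = 0.05
    drift_um_s: list[float] = Field(default_factory=lambda: [0.0, 0.0])


class FilterConfig(_Strict):
    n_discard: int = 10


class LocalizeConfig(_Strict):
    corr_threshold: float = 0.7
    interp_factor: int = 6
    max_per_frame: int = 200
    use_vesselness: bool = True


class TrackConfig(_Strict):
    max_speed_mm_s: float = 100.0
    min_len: int = 10


class MapsConfig(_Strict):
    w_t: float = 5.0
    step_t: float = 1.0
    sr_factor: int = 16
    min_pixel_count: int = 5
    drift_correction: bool = False
    drift_chunk_s: float = 10.0


class FunctionalConfig(_Strict):
    method: str = "svd"  # or "correlation"
    rho_min: float = 0.2  # split-half consistency gate for mode detection


class PipelineConfig(_Strict):
    seed: int = 0
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    filter: FilterConfig = Field(default_factory=FilterConfig)
    localize: LocalizeConfig = Field(default_factory=LocalizeConfig)
    track: TrackConfig = Field(default_factory=TrackConfig)
    maps: MapsConfig = Field(default_factory=MapsConfig)
    functional: FunctionalConfig = Field(default_factory=FunctionalConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))


def flux_study_segments(
    grid_nz: int = 12,
    grid_nx: int = 12,
    rate_mb_s: float = 0.4,
    n_activated: int = 6,
    n_control: int = 2,
) -> list[dict]:
    """Flux-recovery study: parallel descending vessels at the stated
    baseline arrival rate (0.4 MB/s, the typical small-vessel baseline
    flux), most activated and some control. Several vessels carry the
    same programmed rate so rate estimates pool independent arrivals
    (a single 0.4 MB/s vessel leaves ~13 % Poisson error on a 20-pattern
    rate ratio)."""
    depth = grid_nz * 100.0
    width = grid_nx * 110.0
    n = n_activated + n_control
    cols = np.linspace(0.08, 0.92, n) if n > 1 else [0.5]
    out = []
    for k in range(n):
        out.append(
            {
                "points_um": [[0.05 * depth, cols[k] * width], [0.95 * depth, cols[k] * width]],
                "radius_um": 12.0,
                "speed_mm_s": 8.0,
                "rate_mb_s": rate_mb_s,
                "activated": k < n_activated,
            }
        )
    return out


def weak_activation_segments(
    grid_nz: int = 12, grid_nx: int = 12, n_thin: int = 8, rate_mb_s: float = 0.4
) -> list[dict]:
    """Repetition-dependence study: a bed of thin activated capillaries
    (5 µm radius, 0.4 MB/s each — the small-vessel baseline flux regime)
    between two denser unmodulated feeding vessels. An activated *region*
    of many small vessels, not a single line, is what the repetition
    analysis addresses."""
    depth = grid_nz * 100.0
    width = grid_nx * 110.0
    out = [
        {
            "points_um": [[0.1 * depth, 0.15 * width], [0.9 * depth, 0.15 * width]],
            "radius_um": 15.0,
            "speed_mm_s": 10.0,
            "rate_mb_s": 2.0,
            "activated": False,
        },
        {
            "points_um": [[0.9 * depth, 0.85 * width], [0.1 * depth, 0.85 * width]],
            "radius_um": 15.0,
            "speed_mm_s": 8.0,
            "rate_mb_s": 2.0,
            "activated": False,
        },
    ]
    for k in range(n_thin):
        x = (0.3 + 0.4 * k / max(n_thin - 1, 1)) * width
        out.append(
            {
                "points_um": [[0.25 * depth, x], [0.75 * depth, x + 40.0]],
                "radius_um": 5.0,
                "speed_mm_s": 3.0,
                "rate_mb_s": rate_mb_s,
                "activated": True,
            }
        )
    return out


def default_two_vessel_segments(grid_nz: int = 16, grid_nx: int = 16) -> list[dict]:
    """A minimal study phantom: one activated descending arteriole, one
    control ascending venule and one activated intraparenchymal branch,
    inside a grid_nz x grid_nx coarse field (100 x 110 µm pitch)."""
    depth = grid_nz * 100.0
    width = grid_nx * 110.0
    x1, x2, x3 = 0.25 * width, 0.75 * width, 0.45 * width
    return [
        {
            "points_um": [[0.05 * depth, x1], [0.95 * depth, x1]],
            "radius_um": 15.0,
            "speed_mm_s": 10.0,
            "rate_mb_s": 1.0,
            "activated": True,
        },
        {
            "points_um": [[0.95 * depth, x2], [0.05 * depth, x2]],
            "radius_um": 15.0,
            "speed_mm_s": 8.0,
            "rate_mb_s": 1.0,
            "activated": False,
        },
        {
            "points_um": [[0.5 * depth, x1], [0.55 * depth, x3]],
            "radius_um": 6.0,
            "speed_mm_s": 3.0,
            "rate_mb_s": 0.4,
            "activated": True,
        },
    ]
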