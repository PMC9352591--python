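"""Image grids for coarse (probe) and super-resolved reconstruction pixels.

Conventions used throughout the package: z is depth (increasing downward),
x is lateral; positions are in micrometres with the origin at the top-left
corner of the grid. Pixel (i, j) spans the half-open interval
[i*pitch, (i+1)*pitch) so a position exactly on a pixel boundary belongs to
the higher-index pixel, and the pixel centre sits at (i + 0.5) * pitch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: default probe pixel pitch, µm (axial z, lateral x)
COARSE_PITCH_UM = (100.0, 110.0)
#: default super-resolution factor (super pitch = coarse pitch / 16)
SR_FACTOR = 16


@dataclass(frozen=True)
class Grid:
    """A regular 2D pixel grid in (z, x) with physical pitch in µm."""

    nz: int
    nx: int
    pitch_z_um: float
    pitch_x_um: float

    def __post_init__(self) -> None:
        if self.nz < 1 or self.nx < 1:
            raise ValueError("grid must have at least one pixel per axis")
        if self.pitch_z_um <= 0 or self.pitch_x_um <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nz, self.nx)

    @property
    def extent_um(self) -> tuple[float, float]:
        """Physical size (z, x) of the field of view in µm."""
        return (self.nz * self.pitch_z_um, self.nx * self.pitch_x_um)

    @property
    def pixel_area_um2(self) -> float:
        return self.pitch_z_um * self.pitch_x_um

    def super_grid(self, sr_factor: int = SR_FACTOR) -> "Grid":
        """The super-resolved grid covering the same field of view."""
        return Grid(
            nz=self.nz * sr_factor,
            nx=self.nx * sr_factor,
            pitch_z_um=self.pitch_z_um / sr_factor,
            pitch_x_um=self.pitch_x_um / sr_factor,
        )

    def pos_to_index(self, z_um, x_um):
        """Nearest-pixel indices for positions in µm (half-up at boundaries).

        Because pixel i spans [i*p, (i+1)*p), flooring position/pitch is the
        nearest-centre rule, and a position exactly on a boundary lands in
        the higher-index pixel.
        """
        iz = np.floor(np.asarray(z_um, dtype=float) / self.pitch_z_um).astype(np.int64)
        ix = np.floor(np.asarray(x_um, dtype=float) / self.pitch_x_um).astype(np.int64)
        return iz, ix

    def index_center(self, iz, ix):
        """Physical centre (µm) of pixel indices."""
        z = (np.asarray(iz, dtype=float) + 0.5) * self.pitch_z_um
        x = (np.asarray(ix, dtype=float) + 0.5) * self.pitch_x_um
        return z, x

    def contains(self, z_um, x_um):
        z = np.asarray(z_um, dtype=float)
        x = np.asarray(x_um, dtype=float)
        ez, ex = self.extent_um
        return (z >= 0) & (z < ez) & (x >= 0) & (x < ex)


def default_coarse_grid(nz: int = 16, nx: int = 16) -> Grid:
    """Probe-pitch grid (100 µm axial × 110 µm lateral by default)."""
    return Grid(nz=nz, nx=nx, pitch_z_um=COARSE_PITCH_UM[0], pitch_x_um=COARSE_PITCH_UM[1])
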