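"""SVD spatiotemporal clutter filtering of ultrafast frame blocks.

Tissue moves slowly and coherently over a frame block while microbubbles
traverse several pixels, so reshaping the block into a Casorati matrix
(space × time) and discarding the largest singular values removes the
low-rank tissue signal and keeps the bubble echoes. The companion
Power Doppler operation integrates the filtered energy over the block,
which is the standard functional-ultrasound blood-volume proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: default number of singular values discarded for contrast (ULM) blocks
N_DISCARD_ULM = 10
#: default number discarded for Power Doppler (fUS) blocks
N_DISCARD_FUS = 60


@dataclass
class FrameBlock:
    """One block of beamformed compound frames with acquisition metadata.

    ``frames`` has shape (Nz, Nx, Nf) and may be real or complex; time
    stamps of the frames are ``t0 + k / frame_rate``.
    """

    frames: np.ndarray
    frame_rate: float
    pitch_um: tuple[float, float]  # (axial z, lateral x)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3D (Nz, Nx, Nf) array")
        if self.frames.shape[2] < 2:
            raise ValueError("a frame block needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.frame_rate

    def casorati(self) -> np.ndarray:
        """Space × time reshaping (Nz·Nx, Nf) of the block."""
        nz, nx, nf = self.frames.shape
        return self.frames.reshape(nz * nx, nf)


def svd_clutter_filter(block: FrameBlock, n_discard: int = N_DISCARD_ULM) -> FrameBlock:
    """Remove the ``n_discard`` largest singular components of the block.

    The Casorati matrix is decomposed without mean-centering (the first
    mode absorbs the mean); the leading singular values are zeroed and the
    block reconstructed with unchanged shape and metadata.
    """
    nz, nx, nf = block.frames.shape
    bound = min(nz * nx, nf)
    if not 0 <= n_discard < bound:
        raise ValueError(
            f"n_discard must lie in [0, {bound}) for a {nz}x{nx}x{nf} block, got {n_discard}"
        )
    if n_discard == 0:
        return replace(block, frames=block.frames.copy())
    u, s, vh = np.linalg.svd(block.casorati(), full_matrices=False)
    s = s.copy()
    s[:n_discard] = 0.0
    filtered = (u * s) @ vh
    return replace(block, frames=filtered.reshape(nz, nx, nf))


def power_doppler(block: FrameBlock) -> np.ndarray:
    """Per-pixel blood-signal energy: sum of squared magnitude over frames."""
    return np.sum(np.abs(block.frames) ** 2, axis=2)
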