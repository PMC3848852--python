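"""In-memory containers for velocity-encoded acquisitions and velocity cines."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Relative magnitudes used by the phantom renderer (arbitrary units).
MYO_MAGNITUDE = 1.0
LUMEN_MAGNITUDE = 0.05
BACKGROUND_MAGNITUDE = 0.25


def default_encoding_moments() -> np.ndarray:
    """Nine-point balanced first-moment matrix.

    Row 0 is the (zero) reference; rows 1..8 sit at the corners of the
    symmetric cube (+-1, +-1, +-1)/sqrt(3), i.e. unit-norm rows.  The
    normalization is such that a velocity of venc along a unit-moment row
    produces an encoded phase of pi.
    """
    corners = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
        dtype=float,
    ) / np.sqrt(3.0)
    return np.vstack([np.zeros(3), corners])


@dataclass
class EncodedAcquisition:
    """Per-frame complex coil images for each of 9 velocity-encoding points.

    ``complex_images`` has shape ``(9, n_frames, ny, nx, n_coils)`` with
    encoding point 0 the velocity-compensated reference.  ``encoding_moments``
    is the 9x3 gradient first-moment matrix, normalized so that a velocity
    equal to ``venc_cm_s`` along a unit-moment row yields phase pi.
    """

    complex_images: np.ndarray
    encoding_moments: np.ndarray
    venc_cm_s: float
    frame_ms: float
    pixel_mm: float
    fov_rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.complex_images.ndim != 5 or self.complex_images.shape[0] != 9:
            raise ValueError(
                "complex_images must have shape (9, frames, y, x, coils); "
                f"got {self.complex_images.shape}"
            )
        self.encoding_moments = np.asarray(self.encoding_moments, dtype=float)
        if self.encoding_moments.shape != (9, 3):
            raise ValueError("encoding_moments must be 9x3")
        diff = self.encoding_moments[1:] - self.encoding_moments[0]
        if np.linalg.matrix_rank(diff) != 3:
            raise ValueError("encoding moment differences must span 3D")

    @property
    def n_frames(self) -> int:
        return self.complex_images.shape[1]

    @property
    def n_coils(self) -> int:
        return self.complex_images.shape[4]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.complex_images.shape[2:4]


@dataclass
class VelocityCine:
    """Three-component velocity field per frame with grid/timing metadata.

    ``velocity`` has shape ``(n_frames, ny, nx, 3)`` in cm/s, components
    ordered (x, y, z=through-plane).  ``n_frames_cycle`` marks the frame
    count of one cardiac cycle (acquisitions may overshoot the r-r interval).
    """

    velocity: np.ndarray
    magnitude: np.ndarray
    venc_cm_s: float
    frame_ms: float
    pixel_mm: float
    n_frames_cycle: int
    fov_rotation_deg: float = 0.0
    wrapped: np.ndarray | None = None
    low_signal: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.velocity.ndim != 4 or self.velocity.shape[3] != 3:
            raise ValueError("velocity must have shape (frames, y, x, 3)")
        if not np.all(np.isfinite(self.velocity)):
            raise ValueError("velocity must be finite")
        if self.frame_ms <= 0:
            raise ValueError("frame_ms must be positive")
        if self.n_frames_cycle > self.n_frames:
            raise ValueError("n_frames_cycle cannot exceed total frames")

    @property
    def n_frames(self) -> int:
        return self.velocity.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.velocity.shape[1:3]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_ms

    @property
    def cycle_ms(self) -> float:
        return self.n_frames_cycle * self.frame_ms

    def trimmed(self) -> "VelocityCine":
        """Return a copy restricted to the frames of one cardiac cycle."""
        t = self.n_frames_cycle
        return VelocityCine(
            velocity=self.velocity[:t],
            magnitude=self.magnitude[:t],
            venc_cm_s=self.venc_cm_s,
            frame_ms=self.frame_ms,
            pixel_mm=self.pixel_mm,
            n_frames_cycle=t,
            fov_rotation_deg=self.fov_rotation_deg,
            wrapped=None if self.wrapped is None else self.wrapped[:t],
            low_signal=None if self.low_signal is None else self.low_signal[:t],
        )
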