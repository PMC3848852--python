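"""Image-grid coordinate conventions shared across the package.

Pixels are indexed 0-based, sampled at their centres.  x increases with
column, y with row; physical coordinates are millimetres relative to the
grid centre: ``mm = (index - (N - 1) / 2) * pixel_mm``.  Angles are
``atan2(y_mm, x_mm)``; the default circumferential counting direction is
increasing angle.
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi

#: 1 cm/s expressed in mm/ms (positions are mm, frame spacing is ms).
CM_PER_S_IN_MM_PER_MS = 0.01


def pixel_centers_mm(n: int, pixel_mm: float) -> np.ndarray:
    """Physical coordinates (mm) of the *n* pixel centres along one axis."""
    return (np.arange(n) - (n - 1) / 2.0) * pixel_mm


def mm_grid(n: int, pixel_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(X, Y)`` meshgrids of pixel-centre coordinates in mm.

    Arrays are shaped ``(n, n)`` and indexed ``[row, col]`` = ``[y, x]``.
    """
    c = pixel_centers_mm(n, pixel_mm)
    X, Y = np.meshgrid(c, c)
    return X, Y


def mm_to_index(coord_mm: np.ndarray, n: int, pixel_mm: float) -> np.ndarray:
    """Nearest-neighbour pixel index for physical coordinates (float -> int)."""
    return np.rint(coord_mm / pixel_mm + (n - 1) / 2.0).astype(np.intp)


def wrap_angle(theta: np.ndarray) -> np.ndarray:
    """Map angles into [0, 2*pi)."""
    return np.mod(theta, TWO_PI)


def sector_index(
    theta: np.ndarray,
    theta_ref: float,
    n_sectors: int,
    direction: int = 1,
) -> np.ndarray:
    """Circumferential sector of each angle.

    ``direction=+1`` counts sectors with increasing angle starting at
    ``theta_ref`` (sector 0 covers the first ``2*pi/n`` wedge past the
    reference ray); ``-1`` counts the other way.  A point exactly on the
    reference ray belongs to sector 0.
    """
    frac = wrap_angle(direction * (np.asarray(theta) - theta_ref)) / TWO_PI
    idx = np.floor(frac * n_sectors).astype(np.intp)
    return np.clip(idx, 0, n_sectors - 1)
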