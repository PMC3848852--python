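"""Fourier tracking: closed per-pixel myocardial trajectories.

Every myocardial pixel at the chosen origin frame (end-diastole or
end-systole) is integrated forward and backward through the cycle with
explicit two-stage (Heun) steps, looking velocities up by nearest neighbour
in space and frame-wise in time.  The two passes are blended with
linear-in-time weights,

    x(t) = (1 - t'/T) * x_fwd(t) + (t'/T) * x_bwd(t),

where t' is the time elapsed from the origin modulo the cycle: the weights
hand over from the forward to the backward estimate across the cycle and
enforce *exact* closure, x(origin + T) = x(origin), the defining property of
periodic (Fourier) trajectory estimation from cine velocity data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._coords import CM_PER_S_IN_MM_PER_MS, pixel_centers_mm
from .containers import VelocityCine
from .geometry import SegmentModel


class TrackingError(RuntimeError):
    pass


@dataclass
class TrajectorySet:
    """Closed motion paths seeded at every mask pixel of the origin frame.

    ``paths`` has shape ``(n_seeds, T + 1, 2)`` mm; column ``j`` is the
    position at frame ``(origin_frame + j) mod T`` and column ``T`` repeats
    the origin position (closure).  ``valid`` flags paths that never left
    the field of view (and, after filtering, never left the mask).
    """

    origin_frame: int
    seeds_px: np.ndarray  # (n_seeds, 2) int (row, col)
    paths: np.ndarray  # (n_seeds, T + 1, 2) mm
    valid: np.ndarray  # (n_seeds,) bool
    n_frames_cycle: int
    frame_ms: float
    pixel_mm: float

    def positions_at(self, frame: int) -> np.ndarray:
        """Positions (mm) of all seeds at an absolute frame index."""
        j = (frame - self.origin_frame) % self.n_frames_cycle
        return self.paths[:, j]


def _nn_lookup(vel_frame: np.ndarray, pos_mm: np.ndarray, n: int, pixel_mm: float):
    """Nearest-neighbour in-plane velocity (cm/s) at arbitrary positions."""
    idx = np.rint(pos_mm / pixel_mm + (n - 1) / 2.0).astype(np.intp)
    inside = np.all((idx >= 0) & (idx < n), axis=-1)
    idx_c = np.clip(idx, 0, n - 1)
    v = vel_frame[idx_c[:, 1], idx_c[:, 0], :2]  # rows are y, cols are x
    return v, inside


def fourier_track(
    cine: VelocityCine,
    model: SegmentModel,
    origin_frame: int,
    closure: bool = True,
) -> TrajectorySet:
    """Track all mask pixels of ``origin_frame`` through one cycle.

    ``closure=False`` keeps the pure forward integration (diagnostics only).
    Velocity is looked up wherever the path currently is, inside the mask or
    not — paths are judged by the mask test afterwards, not censored during
    integration.  Positions leaving the FOV mark the path invalid.
    """
    T = cine.n_frames_cycle
    if not 0 <= origin_frame < T:
        raise TrackingError("origin frame outside the cardiac cycle")
    n = cine.grid_shape[0]
    pix = cine.pixel_mm
    dt = cine.frame_ms
    vel = cine.velocity

    rows, cols = np.nonzero(model.mask[origin_frame])
    seeds_px = np.stack([rows, cols], axis=-1)
    centers = pixel_centers_mm(n, pix)
    seeds_mm = np.stack([centers[cols], centers[rows]], axis=-1)  # (x, y)
    S = seeds_mm.shape[0]
    if S == 0:
        raise TrackingError("no seeds: empty mask at origin frame")

    scale = dt * CM_PER_S_IN_MM_PER_MS  # cm/s -> mm per frame step
    valid = np.ones(S, dtype=bool)

    # two-stage (Heun) steps: predictor with this frame's velocity,
    # corrector averaging in the next frame's velocity at the predicted point
    fwd = np.empty((S, T + 1, 2))
    fwd[:, 0] = seeds_mm
    for j in range(T):
        f0 = (origin_frame + j) % T
        f1 = (origin_frame + j + 1) % T
        v0, inside = _nn_lookup(vel[f0], fwd[:, j], n, pix)
        valid &= inside
        v1, inside = _nn_lookup(vel[f1], fwd[:, j] + v0 * scale, n, pix)
        valid &= inside
        fwd[:, j + 1] = fwd[:, j] + 0.5 * (v0 + v1) * scale

    bwd = np.empty((S, T + 1, 2))
    bwd[:, T] = seeds_mm
    for j in range(T, 0, -1):
        f0 = (origin_frame + j) % T
        f1 = (origin_frame + j - 1) % T
        v0, inside = _nn_lookup(vel[f0], bwd[:, j], n, pix)
        valid &= inside
        v1, inside = _nn_lookup(vel[f1], bwd[:, j] - v0 * scale, n, pix)
        valid &= inside
        bwd[:, j - 1] = bwd[:, j] - 0.5 * (v0 + v1) * scale

    if closure:
        w = (np.arange(T + 1) / T)[None, :, None]
        paths = (1.0 - w) * fwd + w * bwd
    else:
        paths = fwd

    return TrajectorySet(
        origin_frame=origin_frame,
        seeds_px=seeds_px,
        paths=paths,
        valid=valid,
        n_frames_cycle=T,
        frame_ms=dt,
        pixel_mm=pix,
    )


def filter_trajectories(traj: TrajectorySet, model: SegmentModel) -> TrajectorySet:
    """Discard trajectories that travel out of the myocardial mask.

    The user-defined mask is the region between the per-frame epicardial and
    endocardial contours, so the test is a point-in-polygon check of the
    continuous path position at every frame (rounding to the pixel raster
    would spuriously discard wall-adherent boundary paths).  Surviving paths
    are not smoothed or otherwise filtered.
    """
    import shapely
    from shapely.geometry import Polygon

    T = traj.n_frames_cycle
    ok = traj.valid.copy()
    for j in range(T):
        f = min((traj.origin_frame + j) % T, model.n_frames - 1)
        epi = Polygon(np.asarray(model.epi_polygons[f]))
        endo = Polygon(np.asarray(model.endo_polygons[f]))
        p = traj.paths[:, j]
        ok &= shapely.contains_xy(epi, p[:, 0], p[:, 1])
        ok &= ~shapely.contains_xy(endo, p[:, 0], p[:, 1])
    if not ok.any():
        raise TrackingError("tracking failed: all trajectories left the mask")
    return TrajectorySet(
        origin_frame=traj.origin_frame,
        seeds_px=traj.seeds_px,
        paths=traj.paths,
        valid=ok,
        n_frames_cycle=T,
        frame_ms=traj.frame_ms,
        pixel_mm=traj.pixel_mm,
    )
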