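"""Bulk-motion correction, cardiopolar decomposition and waveform extraction.

Sign convention (prominent because the opposite is also common): the radial
velocity is positive for motion *toward* the LV centre, i.e. contraction is
positive.  Tangential velocity is positive in the circumferential counting
direction of the segment model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.stats import pearsonr

from ._coords import mm_grid
from .containers import VelocityCine
from .geometry import SegmentModel


@dataclass
class WaveformSet:
    """Global and per-segment waveforms of one velocity component."""

    global_: np.ndarray  # (frames,)
    regional: np.ndarray  # (n_segments, frames)
    component: str  # radial | tangential | longitudinal
    time_ms: np.ndarray
    filled: np.ndarray | None = None  # (n_segments, frames) bool: carried values

    @property
    def n_segments(self) -> int:
        return self.regional.shape[0]


@dataclass
class KeyTimepoints:
    t_peak_systole: int
    t_end_systole: int
    t_ED: int


def subtract_bulk_motion(cine: VelocityCine, model: SegmentModel) -> VelocityCine:
    """Remove the mask-mean in-plane velocity per frame (bulk cardiac motion).

    The through-plane component is untouched.
    """
    v = cine.velocity.copy()
    for f in range(cine.n_frames):
        m = model.mask[min(f, model.n_frames - 1)]
        if not m.any():
            continue
        v[f, ..., 0] -= v[f, ..., 0][m].mean()
        v[f, ..., 1] -= v[f, ..., 1][m].mean()
    return VelocityCine(
        velocity=v,
        magnitude=cine.magnitude,
        venc_cm_s=cine.venc_cm_s,
        frame_ms=cine.frame_ms,
        pixel_mm=cine.pixel_mm,
        n_frames_cycle=cine.n_frames_cycle,
        fov_rotation_deg=cine.fov_rotation_deg,
        wrapped=cine.wrapped,
        low_signal=cine.low_signal,
    )


@dataclass
class PolarVelocities:
    """Per-pixel cardiopolar decomposition, contraction-positive radial."""

    radial: np.ndarray  # (frames, y, x) cm/s, toward centre positive
    tangential: np.ndarray  # (frames, y, x) cm/s, counting-direction positive
    longitudinal: np.ndarray  # (frames, y, x) cm/s
    at_center: np.ndarray  # (frames, y, x) bool, undefined decomposition


def to_cardiopolar(cine: VelocityCine, model: SegmentModel) -> PolarVelocities:
    """Decompose in-plane velocity into radial/tangential about the LV centre.

    Radial is the projection onto the unit vector from the LV centre to the
    pixel with *contraction reported as positive*; tangential is the
    orthogonal in-plane projection, positive in the segment counting
    direction; longitudinal is the through-plane component unchanged.
    """
    n = cine.grid_shape[0]
    X, Y = mm_grid(n, cine.pixel_mm)
    nf = cine.n_frames
    radial = np.zeros((nf, n, n))
    tangential = np.zeros((nf, n, n))
    at_center = np.zeros((nf, n, n), dtype=bool)
    for f in range(nf):
        cx, cy = model.centers[min(f, model.n_frames - 1)]
        dx, dy = X - cx, Y - cy
        r = np.hypot(dx, dy)
        zero = r < 1e-12
        r_safe = np.where(zero, 1.0, r)
        ux, uy = dx / r_safe, dy / r_safe
        vx, vy = cine.velocity[f, ..., 0], cine.velocity[f, ..., 1]
        outward = vx * ux + vy * uy
        radial[f] = np.where(zero, 0.0, -outward)
        # tangential unit vector for +theta is (-uy, ux); flip with direction
        tang = (-vx * uy + vy * ux) * model.direction
        tangential[f] = np.where(zero, 0.0, tang)
        at_center[f] = zero
    return PolarVelocities(
        radial=radial,
        tangential=tangential,
        longitudinal=cine.velocity[..., 2].copy(),
        at_center=at_center,
    )


def extract_waveforms(
    field: np.ndarray,
    model: SegmentModel,
    component: str,
    frame_ms: float,
) -> WaveformSet:
    """Mask-mean global and segment-mean regional waveforms.

    The global waveform is the mean over *all* mask pixels (not the mean of
    segment means).  A segment empty at some frame carries the value from
    the nearest frame where it has data, and is flagged in ``filled``.
    """
    nf = field.shape[0]
    ns = model.n_segments
    global_ = np.zeros(nf)
    regional = np.full((ns, nf), np.nan)
    for f in range(nf):
        m = model.mask[min(f, model.n_frames - 1)]
        seg = model.segmap[min(f, model.n_frames - 1)]
        vals = field[f][m]
        global_[f] = vals.mean() if vals.size else 0.0
        labels = seg[m]
        counts = np.bincount(labels, minlength=ns)
        sums = np.bincount(labels, weights=vals, minlength=ns)
        with np.errstate(invalid="ignore"):
            regional[:, f] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    filled = np.isnan(regional)
    if filled.any():
        frames = np.arange(nf)
        for s in range(ns):
            bad = filled[s]
            if bad.all():
                regional[s] = 0.0
                continue
            if bad.any():
                regional[s, bad] = np.interp(
                    frames[bad], frames[~bad], regional[s, ~bad]
                )
    return WaveformSet(
        global_=global_,
        regional=regional,
        component=component,
        time_ms=np.arange(nf) * frame_ms,
        filled=filled,
    )


def detect_key_timepoints(
    radial: WaveformSet,
    lumen_area_mm2: np.ndarray,
    t_ED: int,
) -> KeyTimepoints:
    """Peak systole from peak global radial velocity (contraction positive),
    end systole from minimum LV lumen area; ties resolve to the earliest
    frame (argmax/argmin convention)."""
    return KeyTimepoints(
        t_peak_systole=int(np.argmax(radial.global_)),
        t_end_systole=int(np.argmin(lumen_area_mm2)),
        t_ED=int(t_ED),
    )


def _periodic_eval(y: np.ndarray, time: np.ndarray, cycle_ms: float, t_query: np.ndarray):
    """Cubic-spline evaluation of a cycle-periodic sampled curve.

    The samples are tiled over three cycles and splined, so queries anywhere
    within one cycle of the sampled range see a smooth periodic extension.
    """
    t3 = np.concatenate([time - cycle_ms, time, time + cycle_ms])
    y3 = np.concatenate([y, y, y])
    return CubicSpline(t3, y3)(t_query)


@dataclass
class AlignmentResult:
    stretch: float
    correlation: float


def align_and_average(
    run1_waveforms: dict[str, WaveformSet],
    run2_waveforms: dict[str, WaveformSet],
    run1_strain=None,
    run2_strain=None,
    stretch_grid: np.ndarray | None = None,
):
    """Temporal normalization and segment-wise averaging of two acquisitions.

    The second run's time axis is stretched (cubic-spline resampling) by the
    factor on a grid (default 0.80-1.25, step 0.005) that maximizes Pearson
    correlation of the two global radial velocity waveforms; all of run 2's
    waveforms (and strain, when given) are then resampled onto run 1's time
    base and averaged segment-by-segment — segment s with segment s, both
    anchored to their own papillary landmarks, which is how the rotated FOV
    is reconciled.

    Returns ``(averaged_waveforms, averaged_strain, AlignmentResult)``;
    ``averaged_strain`` is None unless both strain sets are given.
    """
    if stretch_grid is None:
        stretch_grid = np.arange(0.80, 1.2501, 0.005)

    w1 = run1_waveforms["radial"]
    w2 = run2_waveforms["radial"]
    t1 = w1.time_ms
    cycle2 = len(w2.global_) * (w2.time_ms[1] - w2.time_ms[0]) if len(w2.time_ms) > 1 else 1.0

    best = (-np.inf, 1.0)
    for alpha in stretch_grid:
        g2 = _periodic_eval(w2.global_, w2.time_ms, cycle2, t1 / alpha)
        r = pearsonr(w1.global_, g2).statistic
        if r > best[0]:
            best = (r, float(alpha))
    corr, alpha = best
    if corr < 0.5:
        warnings.warn(
            f"acquisitions inconsistent: max global-radial correlation {corr:.2f} < 0.5",
            RuntimeWarning,
            stacklevel=2,
        )

    def resample_rows(rows, time):
        return np.stack(
            [_periodic_eval(row, time, cycle2, t1 / alpha) for row in np.atleast_2d(rows)]
        )

    averaged: dict[str, WaveformSet] = {}
    for name, ws1 in run1_waveforms.items():
        ws2 = run2_waveforms[name]
        reg2 = resample_rows(ws2.regional, ws2.time_ms)
        glob2 = resample_rows(ws2.global_, ws2.time_ms)[0]
        averaged[name] = WaveformSet(
            global_=0.5 * (ws1.global_ + glob2),
            regional=0.5 * (ws1.regional + reg2),
            component=ws1.component,
            time_ms=t1,
        )

    averaged_strain = None
    if run1_strain is not None and run2_strain is not None:
        from .strain import StrainCurveSet

        sc2 = resample_rows(run2_strain.Sc, run2_strain.time_ms)
        sc = 0.5 * (run1_strain.Sc + sc2)
        missing = run1_strain.missing | run2_strain.missing
        sc[run1_strain.missing] = sc2[run1_strain.missing]
        sc[run2_strain.missing & ~run1_strain.missing] = run1_strain.Sc[
            run2_strain.missing & ~run1_strain.missing
        ]
        averaged_strain = StrainCurveSet(
            Sc=sc,
            x_s=run1_strain.x_s,
            t_ED=run1_strain.t_ED,
            time_ms=t1,
            origin="averaged",
            missing=missing,
        )

    return averaged, averaged_strain, AlignmentResult(stretch=alpha, correlation=corr)
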