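"""Circumferential Lagrangian strain from trajectory centroids and contours.

Segmental strain follows the chord between the mean positions of the two
*adjacent* segments' trajectories:

    Sc_s(t) = |x_{s-1}(t) - x_{s+1}(t)| / |x_{s-1}(t_ED) - x_{s+1}(t_ED)| - 1

with x_s(t) the mean in-plane position of the valid trajectories seeded in
segment s, and the baseline taken at the first frame of the (trimmed)
cardiac cycle, i.e. end-diastole — because the trajectories are closed,
Sc_s(t_ED) = 0 identically.  The chord (straight-line) distance is used as
written, with no arc-length correction.

A contour-based global strain is provided as an internal control:

    Sc_g(t) = 1/2 [ (L_epi(t) - L_epi(1)) / L_epi(1)
                  + (L_endo(t) - L_endo(1)) / L_endo(1) ]

from the perimeters of the epicardial/endocardial polygons.  On an
incompressible wall it systematically overestimates the magnitude of the
trajectory-derived strain, since wall-thickness change contributes to the
perimeter change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .geometry import SegmentModel
from .tracking import TrajectorySet


class StrainError(ValueError):
    pass


@dataclass
class StrainCurveSet:
    """Segmental and global circumferential strain (dimensionless)."""

    Sc: np.ndarray  # (n_segments, frames)
    x_s: np.ndarray | None  # (n_segments, frames, 2) mean positions, mm
    t_ED: int
    time_ms: np.ndarray
    origin: str  # "ED" | "ES" | "averaged"
    missing: np.ndarray = None  # type: ignore[assignment]  # (n_segments,) bool

    def __post_init__(self) -> None:
        if self.missing is None:
            self.missing = np.zeros(self.Sc.shape[0], dtype=bool)

    @property
    def global_Sc(self) -> np.ndarray:
        """Unweighted mean of the (non-missing) segmental curves."""
        if self.missing.all():
            raise StrainError("all segments missing")
        return self.Sc[~self.missing].mean(axis=0)

    @property
    def n_segments(self) -> int:
        return self.Sc.shape[0]


@dataclass
class ContourStrain:
    L_epi: np.ndarray  # (frames,) mm
    L_endo: np.ndarray  # (frames,) mm
    Sc_g: np.ndarray  # (frames,)
    time_ms: np.ndarray


def segment_paths(traj: TrajectorySet, model: SegmentModel):
    """Mean in-plane position per segment, x_s(t), from valid trajectories.

    Segment membership is fixed at the origin frame.  Returns
    ``(x_s, missing)`` with ``x_s`` of shape ``(n_segments, T, 2)`` (mm,
    columns in *absolute* frame order 0..T-1) and ``missing`` flagging
    segments with zero valid trajectories.
    """
    T = traj.n_frames_cycle
    ns = model.n_segments
    seg_of_seed = model.segmap[traj.origin_frame][
        traj.seeds_px[:, 0], traj.seeds_px[:, 1]
    ]
    x_s = np.zeros((ns, T, 2))
    missing = np.zeros(ns, dtype=bool)
    for s in range(ns):
        sel = (seg_of_seed == s) & traj.valid
        if not sel.any():
            missing[s] = True
            continue
        # reorder path columns to absolute frames
        block = traj.paths[sel][:, :T].mean(axis=0)  # (T, 2), origin-relative
        shift = traj.origin_frame % T
        x_s[s] = np.roll(block, shift, axis=0)
    return x_s, missing


def circumferential_strain(
    x_s: np.ndarray,
    t_ED: int,
    frame_ms: float,
    origin: str,
    missing: np.ndarray | None = None,
) -> StrainCurveSet:
    """Segmental strain from neighbour-centroid chords (indices mod n).

    A segment with missing x_s renders its own strain and that of its two
    neighbours missing.
    """
    ns, T, _ = x_s.shape
    if missing is None:
        missing = np.zeros(ns, dtype=bool)
    chord = np.linalg.norm(np.roll(x_s, 1, axis=0) - np.roll(x_s, -1, axis=0), axis=-1)
    baseline = chord[:, t_ED]
    usable = ~(np.roll(missing, 1) | np.roll(missing, -1) | missing)
    if np.any(baseline[usable] == 0.0):
        raise StrainError("zero baseline chord between neighbour segments")
    sc = np.zeros((ns, T))
    sc[usable] = chord[usable] / baseline[usable, None] - 1.0
    return StrainCurveSet(
        Sc=sc,
        x_s=x_s,
        t_ED=t_ED,
        time_ms=np.arange(T) * frame_ms,
        origin=origin,
        missing=~usable,
    )


def average_dual_origin(
    sc_ed: StrainCurveSet, sc_es: StrainCurveSet
) -> StrainCurveSet:
    """Segment-wise mean of the ED- and ES-origin strain waveforms.

    Where one origin's segment is missing the other's curve is used; a
    segment missing in both stays missing.
    """
    if sc_ed.Sc.shape != sc_es.Sc.shape:
        raise StrainError("strain curve sets must share a time base")
    sc = 0.5 * (sc_ed.Sc + sc_es.Sc)
    only_es = sc_ed.missing & ~sc_es.missing
    only_ed = sc_es.missing & ~sc_ed.missing
    sc[only_es] = sc_es.Sc[only_es]
    sc[only_ed] = sc_ed.Sc[only_ed]
    missing = sc_ed.missing & sc_es.missing
    sc[missing] = 0.0
    return StrainCurveSet(
        Sc=sc,
        x_s=sc_ed.x_s,
        t_ED=sc_ed.t_ED,
        time_ms=sc_ed.time_ms,
        origin="averaged",
        missing=missing,
    )


def mask_strain(
    epi_polygons: list,
    endo_polygons: list,
    frame_ms: float,
    baseline_frame: int = 0,
) -> ContourStrain:
    """Polygon-perimeter global strain (internal control)."""
    L_epi = np.array([Polygon(np.asarray(p)).length for p in epi_polygons])
    L_endo = np.array([Polygon(np.asarray(p)).length for p in endo_polygons])
    if L_epi[baseline_frame] == 0 or L_endo[baseline_frame] == 0:
        raise StrainError("degenerate polygon: zero perimeter")
    sc = 0.5 * (
        (L_epi - L_epi[baseline_frame]) / L_epi[baseline_frame]
        + (L_endo - L_endo[baseline_frame]) / L_endo[baseline_frame]
    )
    return ContourStrain(
        L_epi=L_epi,
        L_endo=L_endo,
        Sc_g=sc,
        time_ms=np.arange(len(L_epi)) * frame_ms,
    )
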