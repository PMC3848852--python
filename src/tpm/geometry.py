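"""Myocardial contours, masks and the papillary-anchored segment division.

The left ventricle is outlined by epicardial and endocardial polygons at a
few user-annotated key frames; intermediate frames are interpolated after
resampling every key polygon to a fixed vertex count with an arc-length
parameterization anchored at the papillary reference angle.  Pixels inside
the epicardium and outside the endocardium form the myocardial mask, divided
into (by default) 32 angular segments counted counterclockwise from the
anterior papillary reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon

from ._coords import mm_grid, sector_index, wrap_angle


class GeometryError(ValueError):
    pass


@dataclass
class ContourSet:
    """The four human post-processing inputs.

    ``epicardial`` / ``endocardial`` map key-frame index -> (N, 2) polygon
    vertices in mm; ``papillary`` holds the two papillary reference points
    (the first defines the segment-0 reference angle); ``foldover`` lists
    polygons excluded from analysis; ``t_last_diastole`` is the annotated
    last-diastolic frame.
    """

    epicardial: dict[int, np.ndarray]
    endocardial: dict[int, np.ndarray]
    papillary: np.ndarray
    foldover: list[np.ndarray] = field(default_factory=list)
    t_last_diastole: int = 0

    def __post_init__(self) -> None:
        if set(self.epicardial) != set(self.endocardial):
            raise GeometryError("epicardial and endocardial key frames must match")
        if len(self.epicardial) < 1:
            raise GeometryError("at least one key frame is required")
        self.papillary = np.asarray(self.papillary, dtype=float).reshape(2, 2)
        for frames in (self.epicardial, self.endocardial):
            for f, poly in frames.items():
                frames[f] = np.asarray(poly, dtype=float)
                if frames[f].ndim != 2 or frames[f].shape[0] < 3:
                    raise GeometryError(f"polygon at frame {f} needs >=3 vertices")
        for f in self.epicardial:
            epi = Polygon(self.epicardial[f])
            endo = Polygon(self.endocardial[f])
            if not epi.is_simple or not endo.is_simple:
                raise GeometryError(f"self-intersecting contour at frame {f}")
            if not epi.contains(endo):
                raise GeometryError(
                    f"endocardial contour not inside epicardial at frame {f}"
                )

    @property
    def key_frames(self) -> list[int]:
        return sorted(self.epicardial)


def _polygon_centroid(poly: np.ndarray) -> np.ndarray:
    c = Polygon(poly).centroid
    return np.array([c.x, c.y])


def resample_polygon(
    poly: np.ndarray,
    n_vertices: int,
    start_angle: float,
    center: np.ndarray | None = None,
) -> np.ndarray:
    """Arc-length resample a closed polygon to ``n_vertices`` points.

    The first output vertex is the boundary point whose angle about the
    polygon centroid is closest to ``start_angle``; orientation is
    normalized counterclockwise (positive signed area).
    """
    poly = np.asarray(poly, dtype=float)
    if poly.shape[0] < 3:
        raise GeometryError("polygon needs >=3 vertices")
    if center is None:
        center = _polygon_centroid(poly)

    # signed area for orientation
    x, y = poly[:, 0], poly[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area2 < 0:
        poly = poly[::-1]

    # densify by arc length
    ring = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(ring, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        raise GeometryError("degenerate polygon (zero perimeter)")
    dense_s = np.linspace(0.0, total, 8 * max(n_vertices, poly.shape[0]), endpoint=False)
    dense = np.stack(
        [np.interp(dense_s, s, ring[:, 0]), np.interp(dense_s, s, ring[:, 1])], axis=-1
    )

    # anchor: dense point whose centroid angle is closest to start_angle
    ang = np.arctan2(dense[:, 1] - center[1], dense[:, 0] - center[0])
    d = np.abs(wrap_angle(ang - start_angle + np.pi) - np.pi)
    k0 = int(np.argmin(d))
    dense = np.roll(dense, -k0, axis=0)

    # uniform arc-length resample from the anchor
    ring = np.vstack([dense, dense[:1]])
    seg = np.linalg.norm(np.diff(ring, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    out_s = np.linspace(0.0, s[-1], n_vertices, endpoint=False)
    return np.stack(
        [np.interp(out_s, s, ring[:, 0]), np.interp(out_s, s, ring[:, 1])], axis=-1
    )


def interpolate_contours(
    contours: ContourSet,
    n_frames: int,
    n_vertices: int = 256,
):
    """Per-frame epicardial and endocardial polygons.

    Key polygons are resampled to ``n_vertices`` matched vertices (anchored
    at the papillary reference angle) and linearly interpolated across
    frames; frames outside the key range use periodic extension over the
    cycle.  Returns ``(epi_list, endo_list)`` of per-frame (n_vertices, 2)
    arrays.
    """
    keys = contours.key_frames
    if len(keys) < 1:
        raise GeometryError("no key frames")
    ref_center = _polygon_centroid(contours.epicardial[keys[0]])
    ref_angle = float(
        np.arctan2(
            contours.papillary[0, 1] - ref_center[1],
            contours.papillary[0, 0] - ref_center[0],
        )
    )
    epi_key = {
        f: resample_polygon(contours.epicardial[f], n_vertices, ref_angle)
        for f in keys
    }
    endo_key = {
        f: resample_polygon(contours.endocardial[f], n_vertices, ref_angle)
        for f in keys
    }

    # periodic key-frame positions: append the first key one cycle later
    kf = np.array(keys, dtype=float)
    kf_ext = np.concatenate([kf, [kf[0] + n_frames]])

    def interp(frames_dict, f):
        pos = f if f >= kf[0] else f + n_frames
        j = int(np.searchsorted(kf_ext, pos, side="right")) - 1
        j = max(0, min(j, len(kf_ext) - 2))
        f0, f1 = kf_ext[j], kf_ext[j + 1]
        p0 = frames_dict[keys[j % len(keys)]]
        p1 = frames_dict[keys[(j + 1) % len(keys)]]
        w = 0.0 if f1 == f0 else (pos - f0) / (f1 - f0)
        return (1.0 - w) * p0 + w * p1

    epi = [interp(epi_key, f) for f in range(n_frames)]
    endo = [interp(endo_key, f) for f in range(n_frames)]
    return epi, endo


@dataclass
class SegmentModel:
    """Per-frame myocardial mask and angular segment assignment."""

    mask: np.ndarray  # (frames, y, x) bool
    segmap: np.ndarray  # (frames, y, x) int16, -1 outside mask
    centers: np.ndarray  # (frames, 2) LV centre in mm
    lumen_area_mm2: np.ndarray  # (frames,)
    epi_polygons: list
    endo_polygons: list
    pixel_mm: float
    n_segments: int = 32
    direction: int = 1
    theta_ref: float = 0.0

    @property
    def n_frames(self) -> int:
        return self.mask.shape[0]

    def segment_pixel_counts(self, frame: int) -> np.ndarray:
        seg = self.segmap[frame][self.mask[frame]]
        return np.bincount(seg, minlength=self.n_segments)


def rasterize_polygon(poly: np.ndarray, n: int, pixel_mm: float) -> np.ndarray:
    """Boolean mask of pixel centres inside a polygon."""
    X, Y = mm_grid(n, pixel_mm)
    geom = Polygon(np.asarray(poly))
    return shapely.contains_xy(geom, X.ravel(), Y.ravel()).reshape(n, n)


def build_segment_model(
    epi_polygons: list,
    endo_polygons: list,
    papillary: np.ndarray,
    grid_size: int,
    pixel_mm: float,
    n_segments: int = 32,
    direction: int = 1,
    foldover: list | None = None,
    exclude_mask: np.ndarray | None = None,
) -> SegmentModel:
    """Rasterize per-frame masks and assign angular segments.

    The mask holds pixels whose centres lie inside the epicardial and
    outside the endocardial polygon, minus fold-over regions and any
    caller-supplied exclusion (e.g. velocity-wrap flags).  The LV centre is
    the epicardial centroid; segment index is ``floor(n * dtheta / 2pi)``
    with ``dtheta`` counted from the (anterior) papillary reference angle in
    ``direction`` (+1 = counterclockwise, ties to the lower index).  The
    reference angle is evaluated once, against the frame-0 centre.
    """
    n_frames = len(epi_polygons)
    papillary = np.asarray(papillary, dtype=float).reshape(-1, 2)
    X, Y = mm_grid(grid_size, pixel_mm)
    xf, yf = X.ravel(), Y.ravel()

    fold = np.zeros((grid_size, grid_size), dtype=bool)
    for poly in foldover or []:
        fold |= shapely.contains_xy(Polygon(np.asarray(poly)), xf, yf).reshape(
            grid_size, grid_size
        )

    mask = np.zeros((n_frames, grid_size, grid_size), dtype=bool)
    segmap = np.full((n_frames, grid_size, grid_size), -1, dtype=np.int16)
    centers = np.zeros((n_frames, 2))
    lumen = np.zeros(n_frames)

    center0 = _polygon_centroid(epi_polygons[0])
    theta_ref = float(
        np.arctan2(papillary[0, 1] - center0[1], papillary[0, 0] - center0[0])
    )

    for f in range(n_frames):
        epi = Polygon(np.asarray(epi_polygons[f]))
        endo = Polygon(np.asarray(endo_polygons[f]))
        inside_epi = shapely.contains_xy(epi, xf, yf).reshape(grid_size, grid_size)
        inside_endo = shapely.contains_xy(endo, xf, yf).reshape(grid_size, grid_size)
        m = inside_epi & ~inside_endo & ~fold
        if exclude_mask is not None:
            ex = exclude_mask[f] if exclude_mask.ndim == 3 else exclude_mask
            m &= ~ex
        if not m.any():
            raise GeometryError(f"empty myocardial mask at frame {f}")
        c = epi.centroid
        centers[f] = (c.x, c.y)
        lumen[f] = endo.area
        theta = np.arctan2(Y - centers[f, 1], X - centers[f, 0])
        seg = sector_index(theta, theta_ref, n_segments, direction)
        segmap[f][m] = seg[m]
        mask[f] = m

    return SegmentModel(
        mask=mask,
        segmap=segmap,
        centers=centers,
        lumen_area_mm2=lumen,
        epi_polygons=list(epi_polygons),
        endo_polygons=list(endo_polygons),
        pixel_mm=pixel_mm,
        n_segments=n_segments,
        direction=direction,
        theta_ref=theta_ref,
    )
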