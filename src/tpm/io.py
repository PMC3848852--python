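"""Container and annotation file formats.

Acquisition container (HDF5)
----------------------------
Encoded data::

    /encoded/complex   (9, frames, y, x, coils) complex
    /encoded/moments   (9, 3) float
    /meta/venc, /meta/frame_ms, /meta/pixel_mm, /meta/fov_rotation_deg

Pre-reconstructed velocity data::

    /velocity          (frames, y, x, 3) float, cm/s
    /magnitude         (frames, y, x) float
    /meta/...          as above, plus /meta/n_frames_cycle

The schema is package-defined (the formats used on-scanner are vendor
internal and undocumented).

Annotations (plain text)
------------------------
A key-value header (``papillary``, ``t_last_diastole``), then polygon
blocks, each introduced by a single header line (``epicardial <frame>``,
``endocardial <frame>`` or ``foldover``) followed by one ``x_mm y_mm``
vertex per line; blocks are separated by blank lines.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .containers import EncodedAcquisition, VelocityCine
from .geometry import ContourSet


class SchemaError(ValueError):
    pass


class AnnotationError(ValueError):
    pass


def _require(h5: h5py.File, name: str):
    if name not in h5:
        raise SchemaError(f"missing {name}")
    return h5[name]


def write_acquisition(path, acq: EncodedAcquisition) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("encoded/complex", data=acq.complex_images)
        f.create_dataset("encoded/moments", data=acq.encoding_moments)
        meta = f.create_group("meta")
        meta["venc"] = acq.venc_cm_s
        meta["frame_ms"] = acq.frame_ms
        meta["pixel_mm"] = acq.pixel_mm
        meta["fov_rotation_deg"] = acq.fov_rotation_deg


def write_cine(path, cine: VelocityCine) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("velocity", data=cine.velocity)
        f.create_dataset("magnitude", data=cine.magnitude)
        meta = f.create_group("meta")
        meta["venc"] = cine.venc_cm_s
        meta["frame_ms"] = cine.frame_ms
        meta["pixel_mm"] = cine.pixel_mm
        meta["fov_rotation_deg"] = cine.fov_rotation_deg
        meta["n_frames_cycle"] = cine.n_frames_cycle
        if cine.wrapped is not None:
            f.create_dataset("wrapped", data=cine.wrapped)


def read_acquisition(path) -> EncodedAcquisition | VelocityCine:
    """Read a container, dispatching on whether it holds encoded or
    pre-reconstructed velocity data (the latter skips reconstruction)."""
    with h5py.File(path, "r") as f:
        meta_grp = _require(f, "meta")
        for key in ("venc", "frame_ms", "pixel_mm"):
            if key not in meta_grp:
                raise SchemaError(f"missing /meta/{key}")
        venc = float(meta_grp["venc"][()])
        frame_ms = float(meta_grp["frame_ms"][()])
        pixel_mm = float(meta_grp["pixel_mm"][()])
        rot = float(meta_grp["fov_rotation_deg"][()]) if "fov_rotation_deg" in meta_grp else 0.0
        if "encoded" in f:
            enc = f["encoded"]
            if "complex" not in enc:
                raise SchemaError("missing /encoded/complex")
            if "moments" not in enc:
                raise SchemaError("missing /encoded/moments")
            return EncodedAcquisition(
                complex_images=enc["complex"][()],
                encoding_moments=enc["moments"][()],
                venc_cm_s=venc,
                frame_ms=frame_ms,
                pixel_mm=pixel_mm,
                fov_rotation_deg=rot,
            )
        if "velocity" in f:
            vel = f["velocity"][()]
            mag = _require(f, "magnitude")[()]
            ncyc = (
                int(meta_grp["n_frames_cycle"][()])
                if "n_frames_cycle" in meta_grp
                else vel.shape[0]
            )
            wrapped = f["wrapped"][()] if "wrapped" in f else None
            return VelocityCine(
                velocity=vel,
                magnitude=mag,
                venc_cm_s=venc,
                frame_ms=frame_ms,
                pixel_mm=pixel_mm,
                n_frames_cycle=ncyc,
                fov_rotation_deg=rot,
                wrapped=wrapped,
            )
    raise SchemaError("container holds neither /encoded/complex nor /velocity")


def write_annotations(path, contours: ContourSet) -> None:
    lines = ["# tissue-phase-mapping annotations v1"]
    pap = contours.papillary
    lines.append(
        f"papillary: {pap[0, 0]:.6f} {pap[0, 1]:.6f} ; {pap[1, 0]:.6f} {pap[1, 1]:.6f}"
    )
    lines.append(f"t_last_diastole: {contours.t_last_diastole}")
    lines.append("")

    def block(header: str, poly: np.ndarray):
        lines.append(header)
        for x, y in poly:
            lines.append(f"{x:.6f} {y:.6f}")
        lines.append("")

    for f_idx in sorted(contours.epicardial):
        block(f"epicardial {f_idx}", contours.epicardial[f_idx])
        block(f"endocardial {f_idx}", contours.endocardial[f_idx])
    for poly in contours.foldover:
        block("foldover", poly)
    Path(path).write_text("\n".join(lines))


def read_annotations(path) -> ContourSet:
    """Parse the plain-text annotation format into a ContourSet.

    All four human inputs are represented; a missing ``t_last_diastole`` is
    an error because it is a required input.
    """
    text = Path(path).read_text()
    epicardial: dict[int, np.ndarray] = {}
    endocardial: dict[int, np.ndarray] = {}
    foldover: list[np.ndarray] = []
    papillary = None
    t_last_diastole = None

    block_header: str | None = None
    vertices: list[list[float]] = []

    def close_block():
        nonlocal block_header, vertices
        if block_header is None:
            return
        poly = np.asarray(vertices, dtype=float)
        if poly.shape[0] < 3:
            raise AnnotationError(
                f"polygon block '{block_header}' has {poly.shape[0]} vertices (<3)"
            )
        tokens = block_header.split()
        if tokens[0] == "epicardial":
            epicardial[int(tokens[1])] = poly
        elif tokens[0] == "endocardial":
            endocardial[int(tokens[1])] = poly
        elif tokens[0] == "foldover":
            foldover.append(poly)
        else:
            raise AnnotationError(f"unknown polygon block '{block_header}'")
        block_header, vertices = None, []

    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("#"):
            continue
        if not line:
            close_block()
            continue
        if ":" in line and block_header is None:
            key, _, val = line.partition(":")
            key = key.strip()
            if key == "papillary":
                pts = [p.split() for p in val.split(";")]
                papillary = np.asarray(pts, dtype=float)
            elif key == "t_last_diastole":
                t_last_diastole = int(val)
            continue
        parts = line.split()
        if block_header is None:
            block_header = line
        elif len(parts) == 2:
            vertices.append([float(parts[0]), float(parts[1])])
        else:
            raise AnnotationError(f"cannot parse line: {raw!r}")
    close_block()

    if t_last_diastole is None:
        raise AnnotationError("t_last_diastole is a required annotation input")
    if papillary is None:
        raise AnnotationError("papillary reference points are required")
    return ContourSet(
        epicardial=epicardial,
        endocardial=endocardial,
        papillary=papillary,
        foldover=foldover,
        t_last_diastole=t_last_diastole,
    )
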