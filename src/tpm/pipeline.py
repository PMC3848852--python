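"""End-to-end post-processing orchestration.

One acquisition flows through: (reconstruction if encoded) -> contour
interpolation and segment model -> bulk-motion subtraction -> cardiopolar
decomposition -> waveform extraction -> key-timepoint detection ->
dual-origin Fourier tracking -> segmental circumferential strain ->
contour-based control strain.  Two acquisitions of the same slice (rotated
FOV) are processed independently and combined by temporal normalization and
segment-wise averaging as the last step; the regional indices are computed
on the combined data.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import Polygon

from .containers import EncodedAcquisition, VelocityCine
from ._coords import mm_grid
from .geometry import ContourSet, SegmentModel, build_segment_model, interpolate_contours
from .io import read_acquisition, read_annotations
from .kinematics import (
    AlignmentResult,
    KeyTimepoints,
    WaveformSet,
    align_and_average,
    detect_key_timepoints,
    extract_waveforms,
    subtract_bulk_motion,
    to_cardiopolar,
)
from .metrics import RegionalIndices, compute_indices
from .recon import reconstruct
from .strain import (
    ContourStrain,
    StrainCurveSet,
    average_dual_origin,
    circumferential_strain,
    mask_strain,
    segment_paths,
)
from .tracking import TrajectorySet, filter_trajectories, fourier_track


@dataclass
class PipelineConfig:
    """Paths and decided defaults for one pipeline run."""

    acquisitions: list[tuple[str, str]]  # (container, annotations) pairs
    out_dir: str = "."
    ecc_order: int = 1
    n_segments: int = 32
    direction: int = 1
    ddof: int = 1
    stretch_min: float = 0.80
    stretch_max: float = 1.25
    stretch_step: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments < 4 or self.n_segments % 2:
            raise ValueError("segment count must be >= 4 and even")
        for container, annotations in self.acquisitions:
            for p in (container, annotations):
                if not Path(p).exists():
                    raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["acquisitions"] = [tuple(pair) for pair in raw["acquisitions"]]
        return cls(**raw)


@dataclass
class ProcessedAcquisition:
    """Everything one acquisition contributes before segment-wise averaging."""

    cine: VelocityCine  # bulk-corrected, trimmed to one cycle
    model: SegmentModel
    waveforms: dict[str, WaveformSet]
    key: KeyTimepoints
    strain: StrainCurveSet  # dual-origin averaged
    strain_ed: StrainCurveSet
    strain_es: StrainCurveSet
    contour_strain: ContourStrain
    trajectories: dict[str, TrajectorySet]


@dataclass
class PipelineResult:
    runs: list[ProcessedAcquisition]
    waveforms: dict[str, WaveformSet]
    strain: StrainCurveSet
    contour_strain: ContourStrain
    key: KeyTimepoints
    indices: RegionalIndices
    alignment: AlignmentResult | None
    log: list[str] = field(default_factory=list)


def derive_static_mask(
    magnitude: np.ndarray,
    epi_polygons: list,
    pixel_mm: float,
    foldover: list | None = None,
    margin_mm: float = 1.0,
    signal_frac: float = 0.2,
) -> np.ndarray:
    """Static-tissue mask for the background-phase fit.

    Pixels with sustained signal, outside the (buffered) union of the
    epicardial contours over the cycle, minus fold-over regions.
    """
    n = magnitude.shape[1]
    X, Y = mm_grid(n, pixel_mm)
    mean_mag = magnitude.mean(axis=0)
    signal = mean_mag > signal_frac * mean_mag.max()
    heart = shapely.unary_union([Polygon(np.asarray(p)) for p in epi_polygons]).buffer(
        margin_mm
    )
    inside = shapely.contains_xy(heart, X.ravel(), Y.ravel()).reshape(n, n)
    static = signal & ~inside
    for poly in foldover or []:
        fold = shapely.contains_xy(
            Polygon(np.asarray(poly)), X.ravel(), Y.ravel()
        ).reshape(n, n)
        static &= ~fold
    return static


def process_acquisition(
    data: EncodedAcquisition | VelocityCine,
    contours: ContourSet,
    ecc_order: int = 1,
    n_segments: int = 32,
    direction: int = 1,
    log: list[str] | None = None,
) -> ProcessedAcquisition:
    """Process a single acquisition through strain (no averaging)."""
    log = log if log is not None else []

    def note(msg):
        log.append(msg)

    t0 = time.perf_counter()
    if isinstance(data, EncodedAcquisition):
        n_frames = data.n_frames
        epi0, endo0 = interpolate_contours(contours, n_frames)
        static = derive_static_mask(
            np.abs(data.complex_images[0, :, :, :, 0]),
            epi0,
            data.pixel_mm,
            contours.foldover,
        )
        cine = reconstruct(data, static_mask=static, ecc_order=ecc_order)
        note(f"reconstruction: {time.perf_counter() - t0:.1f} s "
             f"(ECC order {ecc_order}, {int(static.sum())} static pixels)")
    else:
        cine = data
        note("velocity container: reconstruction stage skipped")

    cine = cine.trimmed()
    n_frames = cine.n_frames

    epi, endo = interpolate_contours(contours, n_frames)
    model = build_segment_model(
        epi,
        endo,
        contours.papillary,
        cine.grid_shape[0],
        cine.pixel_mm,
        n_segments=n_segments,
        direction=direction,
        foldover=contours.foldover,
        exclude_mask=cine.wrapped,
    )
    note(f"segment model: {n_segments} segments, "
         f"{int(model.mask[0].sum())} mask pixels at frame 0")

    cine = subtract_bulk_motion(cine, model)
    polar = to_cardiopolar(cine, model)
    waveforms = {
        "radial": extract_waveforms(polar.radial, model, "radial", cine.frame_ms),
        "tangential": extract_waveforms(
            polar.tangential, model, "tangential", cine.frame_ms
        ),
        "longitudinal": extract_waveforms(
            polar.longitudinal, model, "longitudinal", cine.frame_ms
        ),
    }
    key = detect_key_timepoints(
        waveforms["radial"], model.lumen_area_mm2, contours.t_last_diastole
    )
    note(f"key timepoints: peak systole frame {key.t_peak_systole}, "
         f"end systole frame {key.t_end_systole}, ED frame {key.t_ED}")

    trajectories = {}
    strains = {}
    for label, origin in (("ED", key.t_ED), ("ES", key.t_end_systole)):
        traj = filter_trajectories(fourier_track(cine, model, origin), model)
        trajectories[label] = traj
        x_s, missing = segment_paths(traj, model)
        strains[label] = circumferential_strain(
            x_s, key.t_ED, cine.frame_ms, origin=label, missing=missing
        )
        note(f"{label}-origin tracking: {int(traj.valid.sum())}/{len(traj.valid)} "
             "trajectories retained")
    strain = average_dual_origin(strains["ED"], strains["ES"])
    cstrain = mask_strain(epi, endo, cine.frame_ms, baseline_frame=key.t_ED)
    note(f"acquisition processed in {time.perf_counter() - t0:.1f} s")

    return ProcessedAcquisition(
        cine=cine,
        model=model,
        waveforms=waveforms,
        key=key,
        strain=strain,
        strain_ed=strains["ED"],
        strain_es=strains["ES"],
        contour_strain=cstrain,
        trajectories=trajectories,
    )


def combine_runs(
    run1: ProcessedAcquisition,
    run2: ProcessedAcquisition,
    stretch_grid: np.ndarray | None = None,
    log: list[str] | None = None,
):
    """Temporal normalization + segment-wise averaging of two acquisitions."""
    log = log if log is not None else []
    waveforms, strain, alignment = align_and_average(
        run1.waveforms,
        run2.waveforms,
        run1.strain,
        run2.strain,
        stretch_grid=stretch_grid,
    )
    key = detect_key_timepoints(
        waveforms["radial"], run1.model.lumen_area_mm2, run1.key.t_ED
    )
    log.append(
        f"segment-wise averaging: stretch {alignment.stretch:.3f}, "
        f"global radial correlation {alignment.correlation:.3f}"
    )
    return waveforms, strain, key, alignment


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full post-processing chain and write the result bundle.

    Deterministic for a fixed config: every stage is a pure function of the
    container plus annotations.  Outputs ``waveforms.csv``, ``strain.csv``,
    ``indices.csv`` and ``run.log`` under ``config.out_dir``.
    """
    log: list[str] = [f"pipeline config: {config}"]
    runs = []
    for container, annotations in config.acquisitions:
        log.append(f"processing {container} with {annotations}")
        data = read_acquisition(container)
        contours = read_annotations(annotations)
        runs.append(
            process_acquisition(
                data,
                contours,
                ecc_order=config.ecc_order,
                n_segments=config.n_segments,
                direction=config.direction,
                log=log,
            )
        )

    alignment = None
    if len(runs) == 2:
        waveforms, strain, key, alignment = combine_runs(
            runs[0],
            runs[1],
            stretch_grid=np.arange(
                config.stretch_min, config.stretch_max + 1e-9, config.stretch_step
            ),
            log=log,
        )
    elif len(runs) == 1:
        log.append("single acquisition: temporal alignment and segment-wise "
                   "averaging skipped")
        waveforms, strain, key = runs[0].waveforms, runs[0].strain, runs[0].key
    else:
        raise ValueError("pipeline expects one or two acquisitions")

    indices = compute_indices(waveforms["radial"], strain, key, ddof=config.ddof)
    result = PipelineResult(
        runs=runs,
        waveforms=waveforms,
        strain=strain,
        contour_strain=runs[0].contour_strain,
        key=key,
        indices=indices,
        alignment=alignment,
        log=log,
    )
    write_result_bundle(result, config.out_dir)
    return result


def write_result_bundle(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for name, ws in result.waveforms.items():
        for f, t in enumerate(ws.time_ms):
            rows.append((name, "global", f, t, ws.global_[f]))
            for s in range(ws.n_segments):
                rows.append((name, s, f, t, ws.regional[s, f]))
    pd.DataFrame(
        rows, columns=["component", "segment", "frame", "time_ms", "velocity_cm_per_s"]
    ).to_csv(out / "waveforms.csv", index=False, float_format="%.10g")

    sc = result.strain
    rows = []
    for f, t in enumerate(sc.time_ms):
        rows.append(("global", f, t, sc.global_Sc[f] * 100.0))
        for s in range(sc.n_segments):
            rows.append((s, f, t, sc.Sc[s, f] * 100.0))
    pd.DataFrame(
        rows, columns=["segment", "frame", "time_ms", "sc_percent_strain"]
    ).to_csv(out / "strain.csv", index=False, float_format="%.10g")

    pd.DataFrame([result.indices.as_dict()]).to_csv(
        out / "indices.csv", index=False, float_format="%.10g"
    )
    (out / "run.log").write_text("\n".join(result.log) + "\n")
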