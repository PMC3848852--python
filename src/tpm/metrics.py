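"""Global peaks, regional-function indices and agreement statistics.

The five regional indices:

* dispersion of peak motion — SD over segments of regional radial velocity
  at peak systole (cm/s);
* dispersion of peak strain — SD over segments of regional Sc at
  end-systole (%strain);
* coherence of motion waveforms — mean Pearson correlation of regional vs
  global radial velocity tracings;
* dispersion of motion waveforms — SD of those correlations;
* index of dyssynchrony — SD over segments of the cross-correlation time
  delay of each regional waveform relative to the global waveform (ms).

The sample (n-1) standard deviation is used throughout by default
(configurable via ``ddof``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.stats import pearsonr, ttest_ind

from .kinematics import KeyTimepoints, WaveformSet
from .strain import StrainCurveSet


@dataclass
class RegionalIndices:
    peak_global_radial_max_cm_s: float
    peak_global_radial_min_cm_s: float
    peak_global_Sc_percent: float
    dispersion_peak_motion_cm_s: float
    dispersion_peak_strain_percent: float
    coherence_motion: float
    dispersion_motion_waveforms: float
    dyssynchrony_index_ms: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def dispersion_of_peak_motion(
    radial: WaveformSet, key: KeyTimepoints, ddof: int = 1
) -> float:
    """SD over segments of the regional radial velocity at peak systole."""
    vals = radial.regional[:, key.t_peak_systole]
    vals = vals[np.isfinite(vals)]
    return float(np.std(vals, ddof=ddof))


def dispersion_of_peak_strain(
    sc: StrainCurveSet, key: KeyTimepoints, ddof: int = 1
) -> float:
    """SD over segments of the regional Sc at end-systole, in %strain."""
    vals = sc.Sc[~sc.missing, key.t_end_systole] * 100.0
    return float(np.std(vals, ddof=ddof))


def waveform_coherence(radial: WaveformSet, ddof: int = 1):
    """Mean and SD over segments of corr(regional, global radial velocity).

    Zero-variance waveforms have undefined correlation and are excluded.
    Returns ``(coherence, dispersion, n_excluded)``.
    """
    g = radial.global_
    rs = []
    excluded = 0
    for row in radial.regional:
        if np.std(row) == 0.0 or np.std(g) == 0.0:
            excluded += 1
            continue
        rs.append(pearsonr(row, g).statistic)
    rs = np.asarray(rs)
    return float(rs.mean()), float(np.std(rs, ddof=ddof)), excluded


def _delay_of(row: np.ndarray, g: np.ndarray, frame_ms: float, window_frac: float):
    """Circular cross-correlation delay with quadratic sub-frame refinement."""
    T = len(g)
    w = max(1, int(round(window_frac * T)))
    shifts = np.arange(-w, w + 1)
    gz = (g - g.mean()) / (np.std(g) * np.sqrt(T))
    rz = (row - row.mean()) / (np.std(row) * np.sqrt(T))
    corr = np.array([np.dot(np.roll(rz, -k), gz) for k in shifts])
    j = int(np.argmax(corr))
    delay = shifts[j]
    # parabola through the peak and its neighbours (inside the window)
    if 0 < j < len(shifts) - 1:
        c0, c1, c2 = corr[j - 1], corr[j], corr[j + 1]
        denom = c0 - 2.0 * c1 + c2
        if denom != 0.0:
            delay = delay + 0.5 * (c0 - c2) / denom
    return delay * frame_ms


def dyssynchrony_index(
    radial: WaveformSet,
    ddof: int = 1,
    window_frac: float = 0.25,
) -> float:
    """SD over segments of the regional-vs-global cross-correlation delays.

    The delay of each segment is the circular shift (search window +-25 % of
    the cycle, refined to sub-frame precision by quadratic interpolation of
    the correlation peak) that maximizes correlation with the global radial
    waveform.  Flat waveforms are excluded.
    """
    frame_ms = float(radial.time_ms[1] - radial.time_ms[0])
    g = radial.global_
    delays = [
        _delay_of(row, g, frame_ms, window_frac)
        for row in radial.regional
        if np.std(row) > 0.0
    ]
    return float(np.std(np.asarray(delays), ddof=ddof))


def global_peaks(radial: WaveformSet, sc: StrainCurveSet):
    """Max/min global radial velocity (cm/s) and peak (most negative)
    global Sc (%strain) over the cycle."""
    g = radial.global_
    gs = sc.global_Sc * 100.0
    return float(g.max()), float(g.min()), float(gs[np.argmin(gs)])


def compute_indices(
    radial: WaveformSet,
    sc: StrainCurveSet,
    key: KeyTimepoints,
    ddof: int = 1,
) -> RegionalIndices:
    vmax, vmin, peak_sc = global_peaks(radial, sc)
    coh, coh_sd, _ = waveform_coherence(radial, ddof=ddof)
    return RegionalIndices(
        peak_global_radial_max_cm_s=vmax,
        peak_global_radial_min_cm_s=vmin,
        peak_global_Sc_percent=peak_sc,
        dispersion_peak_motion_cm_s=dispersion_of_peak_motion(radial, key, ddof),
        dispersion_peak_strain_percent=dispersion_of_peak_strain(sc, key, ddof),
        coherence_motion=coh,
        dispersion_motion_waveforms=coh_sd,
        dyssynchrony_index_ms=dyssynchrony_index(radial, ddof),
    )


# -- cross-modality comparison helpers ---------------------------------------


def resample_for_comparison(curve: np.ndarray, n_points: int = 23) -> np.ndarray:
    """Cubic-spline resample one cycle of a curve to n equally spaced points.

    The curve is treated as cycle-periodic (samples at i*T/len spacing); the
    output samples sit at j*T/n.  Resampling a curve already on n points is
    the identity.
    """
    if n_points < 4:
        raise ValueError("need at least 4 resampling points")
    y = np.asarray(curve, dtype=float)
    m = len(y)
    t = np.arange(m) / m  # cycle-normalized sample times
    t3 = np.concatenate([t - 1.0, t, t + 1.0])
    y3 = np.concatenate([y, y, y])
    return CubicSpline(t3, y3)(np.arange(n_points) / n_points)


def synchronize_to_peak(curves: list[np.ndarray], mode: str = "min"):
    """Circularly shift each curve so its extremum lands at index 0.

    ``mode="min"`` aligns to the most negative value (peak global Sc).
    """
    out = []
    for y in curves:
        k = int(np.argmin(y) if mode == "min" else np.argmax(y))
        out.append(np.roll(y, -k))
    return out


def limits_of_agreement(series_a, series_b, ddof: int = 1):
    """Bland-Altman bias and half-width 1.96*SD of paired differences."""
    a = np.asarray(series_a, dtype=float).ravel()
    b = np.asarray(series_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 paired samples")
    d = a - b
    return float(d.mean()), float(1.96 * np.std(d, ddof=ddof))


def group_ttest(group_a, group_b):
    """Two-sample Student's t-test (plumbing for cohort comparisons)."""
    res = ttest_ind(np.asarray(group_a), np.asarray(group_b))
    return float(res.statistic), float(res.pvalue)
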