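"""Multi-coil phase-contrast reconstruction.

Turns nine-point velocity-encoded complex coil images into a 3-component
velocity cine: coil combination by complex-conjugate reference
multiplication, background (eddy-current) phase correction by a low-order
polynomial fit over static tissue, and least-squares decoding of the eight
phase-difference maps.

Phase unwrapping is deliberately not attempted: the protocol's venc exceeds
myocardial velocities, so pixels whose encoded phase approaches +-pi are
flagged as potentially wrapped and excluded from masks downstream.
"""

from __future__ import annotations

import numpy as np

from .containers import EncodedAcquisition, VelocityCine


class ReconstructionError(ValueError):
    pass


class InsufficientStaticRegionError(ReconstructionError):
    pass


def combine_coils(acq: EncodedAcquisition):
    """Coil-combined phase-difference maps and magnitude image.

    For each encoded point e the per-pixel phase is
    ``arg(sum_coils S_e * conj(S_0))`` — the complex-conjugate product
    cancels coil phase and weights coils by reference magnitude.  The
    magnitude image is ``sqrt(sum_coils |S_0|^2)``.

    Returns
    -------
    phase_maps : (8, frames, y, x) float array, encoded points 1..8
    magnitude : (frames, y, x) float array
    low_signal : (frames, y, x) bool array
        Pixels with zero combined reference signal; their phase is set to 0.
    """
    imgs = acq.complex_images.astype(np.complex128, copy=False)
    ref = imgs[0]
    prod = np.einsum("efyxc,fyxc->efyx", imgs[1:], np.conj(ref))
    magnitude = np.sqrt(np.sum(np.abs(ref) ** 2, axis=-1))
    low_signal = magnitude == 0.0
    phase_maps = np.angle(prod)
    phase_maps[:, low_signal] = 0.0
    return phase_maps, magnitude, low_signal


def _poly_basis(X: np.ndarray, Y: np.ndarray, order: int) -> np.ndarray:
    """2D polynomial basis up to total degree `order`, stacked last axis."""
    terms = [
        X**i * Y**j
        for total in range(order + 1)
        for i in range(total, -1, -1)
        for j in [total - i]
    ]
    return np.stack(terms, axis=-1)


def correct_eddy_phase(
    phase_maps: np.ndarray,
    static_mask: np.ndarray,
    exclusion_mask: np.ndarray | None = None,
    order: int = 1,
):
    """Subtract a polynomial background-phase surface per encoded point.

    A 2D polynomial of total degree ``order`` (default 1, the dominant
    eddy-current term) is fitted to each encoded point's temporal-mean phase
    over static, non-excluded pixels, then subtracted from every frame.
    Fold-over-contaminated regions are removed from the fit via
    ``exclusion_mask``.

    Returns ``(corrected_phase_maps, coefficients)`` where ``coefficients``
    has one row of polynomial coefficients per encoded point (constant term
    first, then increasing total degree, x-power-major).
    """
    phase_maps = np.asarray(phase_maps, dtype=float)
    ny, nx = phase_maps.shape[-2:]
    fit_mask = np.asarray(static_mask, dtype=bool)
    if exclusion_mask is not None:
        fit_mask = fit_mask & ~np.asarray(exclusion_mask, dtype=bool)

    # normalized coordinates keep the Vandermonde well conditioned
    cy = np.linspace(-1.0, 1.0, ny)
    cx = np.linspace(-1.0, 1.0, nx)
    X, Y = np.meshgrid(cx, cy)
    basis = _poly_basis(X, Y, order)
    n_coeff = basis.shape[-1]
    if fit_mask.sum() < n_coeff:
        raise InsufficientStaticRegionError(
            f"{int(fit_mask.sum())} static pixels for {n_coeff} polynomial coefficients"
        )

    A = basis[fit_mask]
    mean_phase = phase_maps.mean(axis=1)  # (8, y, x)
    corrected = phase_maps.copy()
    coeffs = np.empty((phase_maps.shape[0], n_coeff))
    for e in range(phase_maps.shape[0]):
        sol, *_ = np.linalg.lstsq(A, mean_phase[e][fit_mask], rcond=None)
        coeffs[e] = sol
        corrected[e] -= np.tensordot(basis, sol, axes=1)[None]
    return corrected, coeffs


def decode_velocities(
    phase_maps: np.ndarray,
    moments: np.ndarray,
    venc_cm_s: float,
    *,
    frame_ms: float,
    pixel_mm: float,
    magnitude: np.ndarray | None = None,
    low_signal: np.ndarray | None = None,
    n_frames_cycle: int | None = None,
    fov_rotation_deg: float = 0.0,
    wrap_eps: float = 1e-3,
) -> VelocityCine:
    """Least-squares decode of the eight phase-difference maps.

    Solves ``(pi / venc) * (M_e - M_0) @ v = phi_e`` per pixel.  The spec'd
    reference-magnitude^2 weighting is uniform across the eight rows of any
    one pixel's system, so it cancels and the plain pseudo-inverse solution
    is identical.  Pixels with any ``|phi_e| > pi * (1 - wrap_eps)`` are
    flagged as potentially wrapped.
    """
    moments = np.asarray(moments, dtype=float)
    diff = moments[1:] - moments[0]
    if np.linalg.matrix_rank(diff) < 3:
        raise ReconstructionError("encoding moment differences are rank deficient")
    A = (np.pi / venc_cm_s) * diff  # (8, 3)
    pinv = np.linalg.pinv(A)  # (3, 8)
    velocity = np.einsum("ke,efyx->fyxk", pinv, phase_maps)
    wrapped = np.any(np.abs(phase_maps) > np.pi * (1.0 - wrap_eps), axis=0)
    if magnitude is None:
        magnitude = np.ones(velocity.shape[:3])
    return VelocityCine(
        velocity=velocity,
        magnitude=magnitude,
        venc_cm_s=venc_cm_s,
        frame_ms=frame_ms,
        pixel_mm=pixel_mm,
        n_frames_cycle=n_frames_cycle or velocity.shape[0],
        fov_rotation_deg=fov_rotation_deg,
        wrapped=wrapped,
        low_signal=low_signal,
    )


def reconstruct(
    acq: EncodedAcquisition,
    static_mask: np.ndarray | None = None,
    exclusion_mask: np.ndarray | None = None,
    ecc_order: int = 1,
    n_frames_cycle: int | None = None,
) -> VelocityCine:
    """Full chain: coil combination, optional ECC, velocity decode."""
    phase_maps, magnitude, low_signal = combine_coils(acq)
    if static_mask is not None:
        phase_maps, _ = correct_eddy_phase(
            phase_maps, static_mask, exclusion_mask, order=ecc_order
        )
    return decode_velocities(
        phase_maps,
        acq.encoding_moments,
        acq.venc_cm_s,
        frame_ms=acq.frame_ms,
        pixel_mm=acq.pixel_mm,
        magnitude=magnitude,
        low_signal=low_signal,
        n_frames_cycle=n_frames_cycle,
        fov_rotation_deg=acq.fov_rotation_deg,
    )
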