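"""Bulk correction, cardiopolar decomposition, waveforms, key timepoints."""

import numpy as np
import pytest

from tpm._coords import mm_grid
from tpm.containers import VelocityCine
from tpm.geometry import SegmentModel
from tpm.kinematics import (
    align_and_average,
    detect_key_timepoints,
    extract_waveforms,
    subtract_bulk_motion,
    to_cardiopolar,
)


def toy_model(n=16, pixel=1.0, r_in=2.0, r_out=6.0, frames=1):
    """Annulus segment model on a small grid, built directly."""
    X, Y = mm_grid(n, pixel)
    r = np.hypot(X, Y)
    theta = np.arctan2(Y, X)
    mask = (r >= r_in) & (r <= r_out)
    seg = np.floor(np.mod(theta, 2 * np.pi) / (2 * np.pi) * 32).astype(np.int16)
    segmap = np.where(mask, seg, -1).astype(np.int16)
    return SegmentModel(
        mask=np.repeat(mask[None], frames, 0),
        segmap=np.repeat(segmap[None], frames, 0),
        centers=np.zeros((frames, 2)),
        lumen_area_mm2=np.full(frames, np.pi * r_in**2),
        epi_polygons=[None] * frames,
        endo_polygons=[None] * frames,
        pixel_mm=pixel,
        n_segments=32,
    )


def toy_cine(velocity, pixel=1.0):
    return VelocityCine(
        velocity=velocity,
        magnitude=np.ones(velocity.shape[:3]),
        venc_cm_s=13.9,
        frame_ms=3.2,
        pixel_mm=pixel,
        n_frames_cycle=velocity.shape[0],
    )


class TestBulkMotion:
    def test_uniform_field_removed(self):
        model = toy_model()
        v = np.zeros((1, 16, 16, 3))
        v[..., 0], v[..., 1], v[..., 2] = 0.8, -0.3, 1.1
        out = subtract_bulk_motion(toy_cine(v), model)
        np.testing.assert_allclose(out.velocity[..., :2], 0.0, atol=1e-12)
        np.testing.assert_allclose(out.velocity[..., 2], 1.1)  # untouched

    def test_zero_mean_field_unchanged(self):
        model = toy_model()
        rng = np.random.default_rng(0)
        v = rng.standard_normal((1, 16, 16, 3))
        m = model.mask[0]
        v[0, ..., 0] -= v[0, ..., 0][m].mean()
        v[0, ..., 1] -= v[0, ..., 1][m].mean()
        out = subtract_bulk_motion(toy_cine(v.copy()), model)
        np.testing.assert_allclose(out.velocity, v, atol=1e-12)


class TestCardiopolar:
    def test_contraction_is_positive_radial(self):
        # pixel right of centre moving toward it: radial +1, tangential 0
        model = toy_model()
        v = np.zeros((1, 16, 16, 3))
        v[..., 0] = -1.0  # leftward everywhere
        polar = to_cardiopolar(toy_cine(v), model)
        X, Y = mm_grid(16, 1.0)
        right = (np.abs(Y) < 1e-9) & (X > 0)
        np.testing.assert_allclose(polar.radial[0][right], 1.0, atol=1e-12)
        np.testing.assert_allclose(polar.tangential[0][right], 0.0, atol=1e-12)
        # and the mirrored pixel sees it as motion away from the centre
        left = (np.abs(Y) < 1e-9) & (X < 0)
        np.testing.assert_allclose(polar.radial[0][left], -1.0, atol=1e-12)

    def test_speed_preserved(self):
        model = toy_model()
        rng = np.random.default_rng(1)
        v = rng.standard_normal((1, 16, 16, 3))
        polar = to_cardiopolar(toy_cine(v), model)
        lhs = polar.radial[0] ** 2 + polar.tangential[0] ** 2
        rhs = v[0, ..., 0] ** 2 + v[0, ..., 1] ** 2
        keep = ~polar.at_center[0]
        np.testing.assert_allclose(lhs[keep], rhs[keep], atol=1e-12)

    def test_rigid_rotation_purely_tangential(self):
        from tpm.phantom import (
            PhantomSpec,
            make_motion_model,
            phantom_annotations,
            render_velocity_cine,
        )
        from tpm.geometry import build_segment_model, interpolate_contours

        spec = PhantomSpec(contraction_amplitude=0.0, longitudinal_amplitude_cm_s=0.0)
        truth = make_motion_model(spec)
        cine = render_velocity_cine(truth, spec)
        ann = phantom_annotations(truth, spec)
        epi, endo = interpolate_contours(ann, spec.n_frames)
        model = build_segment_model(
            epi, endo, ann.papillary, spec.grid_size, spec.pixel_mm
        )
        polar = to_cardiopolar(cine, model)
        assert np.abs(polar.radial[model.mask]).max() < 1e-9


class TestWaveforms:
    def test_constant_field(self):
        model = toy_model()
        field = np.full((1, 16, 16), 2.5)
        ws = extract_waveforms(field, model, "radial", 3.2)
        np.testing.assert_allclose(ws.global_, 2.5)
        np.testing.assert_allclose(ws.regional, 2.5)

    def test_segment_labels_recovered(self):
        model = toy_model()
        field = model.segmap[0].astype(float)[None]
        ws = extract_waveforms(field, model, "radial", 3.2)
        np.testing.assert_allclose(ws.regional[:, 0], np.arange(32))

    def test_global_is_count_weighted_regional_mean(self, vel_run):
        ws = vel_run.waveforms["radial"]
        model = vel_run.model
        for f in (0, 7, 14, 30):
            counts = model.segment_pixel_counts(f)
            weighted = np.sum(counts * ws.regional[:, f]) / counts.sum()
            assert abs(weighted - ws.global_[f]) < 1e-9

    def test_regional_matches_masked_analytic_oracle(self, vel_bundle, vel_run):
        """Pipeline regional waveforms vs independent pixel-centre evaluation
        of the analytic field (annulus-masked, bulk-subtracted)."""
        spec, truth = vel_bundle.spec, vel_bundle.truth
        model = vel_run.model
        X, Y = mm_grid(spec.grid_size, spec.pixel_mm)
        for f in (0, 7, 14, 40):
            m = model.mask[f]
            t = f * spec.frame_ms
            vx, vy, _ = truth.velocity_fn(X[m], Y[m], t)
            r_en, r_ep = truth.boundary_radii(np.arctan2(Y[m], X[m]), t)
            rr = np.hypot(X[m], Y[m])
            inside = (rr >= r_en) & (rr <= r_ep)
            vx, vy = np.where(inside, vx, 0.0), np.where(inside, vy, 0.0)
            vx, vy = vx - vx.mean(), vy - vy.mean()
            cx, cy = model.centers[f]
            dx, dy = X[m] - cx, Y[m] - cy
            rad = -(vx * dx + vy * dy) / np.hypot(dx, dy)
            seg = model.segmap[f][m]
            for s in range(32):
                sel = seg == s
                if sel.any():
                    assert (
                        abs(rad[sel].mean() - vel_run.waveforms["radial"].regional[s, f])
                        < 1e-9
                    )

    def test_global_matches_continuum_oracle(self, vel_bundle, vel_run):
        """Global radial waveform vs the closed-form annulus area-mean."""
        spec, truth = vel_bundle.spec, vel_bundle.truth
        t = np.arange(spec.n_frames) * spec.frame_ms
        cont = truth.segment_radial_velocity(0, t)
        assert np.abs(vel_run.waveforms["radial"].global_ - cont).max() < 0.25

    def test_empty_segment_carries_nearest(self):
        model = toy_model(frames=2)
        model.segmap[1][model.segmap[1] == 3] = 2  # segment 3 empty at frame 1
        field = np.ones((2, 16, 16))
        field[1] = 5.0
        ws = extract_waveforms(field, model, "radial", 3.2)
        assert ws.filled[3, 1]
        assert ws.regional[3, 1] == 1.0  # carried from frame 0


class TestKeyTimepoints:
    def test_phantom_end_systole_at_minimum_area(self, vel_run, default_spec):
        # analytic lumen minimum is at 20% of the cycle
        expected = round(0.2 * default_spec.n_frames)
        assert abs(vel_run.key.t_end_systole - expected) <= 1
        assert vel_run.key.t_ED == 0

    def test_monotone_ramp_and_ties(self):
        ws = extract_waveforms(
            np.arange(5)[:, None, None] * np.ones((5, 16, 16)), toy_model(frames=1), "radial", 3.2
        )
        key = detect_key_timepoints(ws, np.ones(5), 0)
        assert key.t_peak_systole == 4
        assert key.t_end_systole == 0  # constant area: earliest frame wins


class TestAlignAverage:
    def test_identity_run(self, vel_run):
        wf, sc, res = align_and_average(
            vel_run.waveforms, vel_run.waveforms, vel_run.strain, vel_run.strain
        )
        assert abs(res.stretch - 1.0) < 1e-9
        assert res.correlation > 0.999999
        np.testing.assert_allclose(
            wf["radial"].regional, vel_run.waveforms["radial"].regional, atol=1e-9
        )
        np.testing.assert_allclose(sc.Sc, vel_run.strain.Sc, atol=1e-12)

    def test_stretch_recovery(self, vel_run):
        """A second run covering one full cycle in 78 frames (slower heart
        rate) is realigned with the expected stretch 70/78 ~ 0.90."""
        from scipy.interpolate import CubicSpline

        from tpm.kinematics import WaveformSet

        w1 = vel_run.waveforms["radial"]
        t1 = w1.time_ms
        dt = t1[1] - t1[0]
        cycle1 = len(t1) * dt
        t3 = np.concatenate([t1 - cycle1, t1, t1 + cycle1])
        n2 = 78
        # run 2's j-th frame samples the same cycle fraction j/n2
        sample_times = np.arange(n2) * cycle1 / n2

        def as_run2(y):
            y3 = np.concatenate([y, y, y])
            return CubicSpline(t3, y3)(sample_times)

        run2 = {
            name: WaveformSet(
                global_=as_run2(ws.global_),
                regional=np.stack([as_run2(row) for row in ws.regional]),
                component=ws.component,
                time_ms=np.arange(n2) * dt,
            )
            for name, ws in vel_run.waveforms.items()
        }
        _, _, res = align_and_average(vel_run.waveforms, run2)
        assert abs(res.stretch - 70 / 78) <= 0.0075
        assert res.correlation > 0.99

    def test_inconsistent_runs_warn(self, vel_run):
        from tpm.kinematics import WaveformSet

        rng = np.random.default_rng(5)
        noise = {
            name: WaveformSet(
                global_=rng.standard_normal(len(ws.global_)),
                regional=rng.standard_normal(ws.regional.shape),
                component=ws.component,
                time_ms=ws.time_ms,
            )
            for name, ws in vel_run.waveforms.items()
        }
        with pytest.warns(RuntimeWarning, match="inconsistent"):
            align_and_average(vel_run.waveforms, noise)
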