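"""Flow curves, stroke volume, SNR and QP/QS."""

import numpy as np
import pytest

from pc4dflow import (
    PhantomSpec,
    Waveform,
    apply_prospective_truncation,
    apply_temporal_blur,
    compute_flow_curve,
    compute_qp_qs,
    compute_snr,
    generate_phantom,
    reformat_plane,
    segment_vessel,
)
from pc4dflow.errors import ParameterError, SegmentationError
from pc4dflow.fields import PlaneDefinition, Series2D
from pc4dflow.flowquant import VesselContour

from conftest import make_disc_contour


def uniform_series(v_mm_s=100.0, npx=21, ps=2.0, nt=4, cycle_ms=1000.0):
    plane = PlaneDefinition.from_normal((0, 0, 0), (0, 0, 1.0), ps, (npx, npx))
    v = np.full((nt, npx, npx), v_mm_s)
    return Series2D(
        v_through=v, magnitude=np.full_like(v, 100.0),
        valid=np.ones((npx, npx), bool), plane=plane,
        trigger_times_ms=np.arange(nt) * (cycle_ms / nt),
        cycle_ms=cycle_ms, venc=1500.0,
    )


def square_contour(half_mm):
    return VesselContour(polygons=[np.array(
        [[-half_mm, -half_mm], [half_mm, -half_mm], [half_mm, half_mm], [-half_mm, half_mm]]
    )])


class TestComputeFlowCurve:
    def test_uniform_velocity_arithmetic(self):
        # 100 mm/s over 400 mm^2 = 40,000 mm^3/s = 40 ml/s; SV = 40 ml over 1 s.
        series = uniform_series(100.0, npx=41, ps=1.0)
        # 20 x 20 mm square offset half a pixel so it covers exactly 400
        # one-mm^2 pixel centers (no boundary ties).
        contour = VesselContour(polygons=[np.array(
            [[-9.5, -9.5], [10.5, -9.5], [10.5, 10.5], [-9.5, 10.5]]
        )])
        curve = compute_flow_curve(series, contour)
        assert np.allclose(curve.flow_ml_s, 40.0, rtol=1e-9)
        assert curve.stroke_volume_ml == pytest.approx(40.0, rel=1e-9)
        assert curve.peak_flow_ml_s == pytest.approx(40.0, rel=1e-9)

    def test_poiseuille_constant_flow(self, oblique_axis):
        # R = 10 mm, v_max = 1000 mm/s: Q = v_max pi R^2 / 2 = 157.1 ml/s.
        spec = PhantomSpec(
            tube_axis=tuple(oblique_axis), radius=10.0,
            waveform=Waveform(mean_ml_s=157.08, harmonics=()),
        )
        field, _ = generate_phantom(spec)
        plane = PlaneDefinition.from_normal((0, 0, 0), tuple(oblique_axis), 1.0, (45, 45))
        series = reformat_plane(field, plane)
        curve = compute_flow_curve(series, make_disc_contour(14.0))
        assert np.allclose(curve.flow_ml_s, 157.08, rtol=0.02)

    def test_truncated_coverage_sv_fraction(self, oblique_axis):
        spec = PhantomSpec(
            tube_axis=tuple(oblique_axis),
            waveform=Waveform(mean_ml_s=100.0, harmonics=()),
        )
        field, _ = generate_phantom(spec)
        plane = PlaneDefinition.from_normal((0, 0, 0), tuple(oblique_axis), 1.5, (41, 41))
        full = compute_flow_curve(reformat_plane(field, plane), make_disc_contour(21.0))
        trunc_field = apply_prospective_truncation(field, 0.85)
        trunc = compute_flow_curve(
            reformat_plane(trunc_field, plane), make_disc_contour(21.0)
        )
        assert trunc.coverage == "truncated"
        assert trunc.stroke_volume_ml == pytest.approx(0.85 * full.stroke_volume_ml, rel=1e-9)

    def test_linearity_and_sign_reversal(self):
        series = uniform_series(100.0)
        contour = square_contour(8.0)
        base = compute_flow_curve(series, contour)
        series.v_through *= -2.5
        scaled = compute_flow_curve(series, contour)
        assert np.allclose(scaled.flow_ml_s, -2.5 * base.flow_ml_s, rtol=1e-12)
        assert scaled.stroke_volume_ml == pytest.approx(
            -2.5 * base.stroke_volume_ml, rel=1e-12
        )

    def test_blur_preserves_sv_but_not_peak(self, phantom_noise_free, tube_plane):
        # The temporal-blur operator's signature: peak flow drops, full-cycle
        # SV is untouched (mean preservation).
        _, field, _ = phantom_noise_free
        contour = make_disc_contour(21.0)
        base = compute_flow_curve(reformat_plane(field, tube_plane), contour)
        blurred = compute_flow_curve(
            reformat_plane(apply_temporal_blur(field, 5), tube_plane), contour
        )
        assert blurred.peak_flow_ml_s < base.peak_flow_ml_s
        assert abs(blurred.stroke_volume_ml - base.stroke_volume_ml) < 1e-6 * abs(
            base.stroke_volume_ml
        )

    def test_contour_over_invalid_pixels_rejected(self):
        series = uniform_series(100.0, npx=11, ps=2.0)
        series.valid[:3] = False
        series.v_through[:, :3] = np.nan
        with pytest.raises(ParameterError, match="invalid"):
            compute_flow_curve(series, square_contour(10.0))


class TestSegmentVessel:
    def test_contour_area_close_to_disc(self, tube_series):
        contour = segment_vessel(tube_series, (0.0, 0.0), 0.1)
        # threshold at 10% of centerline speed: boundary at r = R*sqrt(0.9)
        area = contour.area_mm2()
        r_true = 15.0
        ring = 2 * np.pi * r_true * tube_series.pixel_size
        assert abs(area - np.pi * r_true**2) < 1.2 * ring

    def test_deterministic(self, tube_series):
        c1 = segment_vessel(tube_series, (0.0, 0.0), 0.1)
        c2 = segment_vessel(tube_series, (0.0, 0.0), 0.1)
        assert np.array_equal(c1.polygons[0], c2.polygons[0])

    def test_seed_in_static_tissue_raises(self, tube_series):
        with pytest.raises(SegmentationError):
            segment_vessel(tube_series, (28.0, 28.0), 0.1)


class TestSNR:
    def test_formula_arithmetic(self):
        # mean vessel magnitude 100, background SD 10 -> 0.655 * 100 / 10.
        mag = np.zeros((2, 10, 10, 1))
        mag[:, :5] = 100.0
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 10.0, size=(2, 5, 10, 1))
        noise = (noise - noise.mean()) / noise.std(ddof=1) * 10.0  # exact sd 10
        mag[:, 5:] = noise
        field_like = type("M", (), {"magnitude": mag})()
        roi_v = np.zeros((10, 10, 1), bool); roi_v[:5] = True
        roi_o = np.zeros((10, 10, 1), bool); roi_o[5:] = True
        assert compute_snr(field_like, roi_v, roi_o) == pytest.approx(6.55, rel=1e-9)

    def test_noise_free_background_rejected(self, phantom_noise_free):
        _, field, truth = phantom_noise_free
        roi_o = field.magnitude[0] == 0  # pure air: zero variance without noise
        with pytest.raises(ParameterError):
            compute_snr(field, truth.blood_pool_mask, roi_o)

    def test_doubling_noise_halves_snr(self, oblique_axis):
        from pc4dflow import noise_sd_for_snr

        nsd = noise_sd_for_snr(15.0, 1500.0)
        snrs = []
        for factor in (1.0, 2.0):
            spec = PhantomSpec(tube_axis=tuple(oblique_axis), noise_sd=factor * nsd, seed=3)
            field, truth = generate_phantom(spec)
            X, Y, _ = field.voxel_centers()
            semi = 0.45 * 40 * 3.0
            air = np.broadcast_to(
                (X / semi) ** 2 + (Y / semi) ** 2 > 1.3, field.grid_shape
            ) & ~truth.blood_pool_mask
            assert air.sum() > 1e3
            snrs.append(compute_snr(field, truth.blood_pool_mask, air))
        assert snrs[0] == pytest.approx(15.0, rel=0.1)
        assert snrs[0] / snrs[1] == pytest.approx(2.0, rel=0.05)


class TestQpQs:
    def test_equal_svs_give_unity(self):
        series = uniform_series(100.0)
        curve = compute_flow_curve(series, square_contour(10.0))
        assert compute_qp_qs(curve, curve) == 1.0

    def test_arithmetic(self):
        series = uniform_series(100.0)
        c = compute_flow_curve(series, square_contour(10.0))
        import dataclasses

        p = dataclasses.replace(c, stroke_volume_ml=103.0)
        s = dataclasses.replace(c, stroke_volume_ml=100.0)
        assert compute_qp_qs(p, s) == pytest.approx(1.03, rel=1e-12)

    def test_nonpositive_sv_rejected(self):
        series = uniform_series(100.0)
        c = compute_flow_curve(series, square_contour(10.0))
        import dataclasses

        bad = dataclasses.replace(c, stroke_volume_ml=-1.0)
        with pytest.raises(ParameterError):
            compute_qp_qs(bad, c)
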