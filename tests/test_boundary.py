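"""Boundary detection: filters, edge index, crossings, spline smoothing."""

import numpy as np
import pytest

import myowave as mw
from myowave import boundary as bd
from myowave.errors import (
    FrameSizeError,
    InsufficientFramesError,
    ValidationError,
)
from .conftest import boundary_mae


class TestSmoothStack:
    def test_preserves_constants(self):
        stack = mw.FrameStack(np.full((6, 20, 30), 37.0), 0.2)
        out = mw.smooth_stack(stack)
        np.testing.assert_allclose(out.frames, 37.0, atol=1e-4)

    def test_impulse_mass_preserved(self):
        frames = np.zeros((7, 21, 31))
        frames[3, 10, 15] = 100.0
        out = mw.smooth_stack(mw.FrameStack(frames, 0.2))
        # Gaussian kernels are normalised, so total mass is conserved
        assert out.frames.sum() == pytest.approx(100.0, rel=1e-4)

    def test_size_one_kernels_are_identity(self):
        rng = np.random.default_rng(3)
        frames = rng.uniform(0, 255, (5, 12, 12))
        params = mw.BoundaryParams(t_kernel=1, s_kernel=1)
        stack = mw.FrameStack(frames, 0.2)
        once = mw.smooth_stack(stack, params)
        twice = mw.smooth_stack(once, params)
        np.testing.assert_allclose(twice.frames, frames, atol=1e-4)

    def test_too_few_frames_rejected(self):
        stack = mw.FrameStack(np.zeros((2, 10, 10)), 0.2)
        with pytest.raises(InsufficientFramesError):
            mw.smooth_stack(stack, mw.BoundaryParams(t_kernel=5))

    def test_rows_not_smoothed(self):
        # a sharp horizontal edge must survive smoothing untouched
        frames = np.zeros((5, 20, 30))
        frames[:, 10:, :] = 200.0
        out = mw.smooth_stack(mw.FrameStack(frames, 0.2))
        np.testing.assert_allclose(out.frames[2, 9, :], 0.0, atol=1e-4)
        np.testing.assert_allclose(out.frames[2, 10, :], 200.0, atol=1e-4)


class TestSobelKernels:
    def test_size3_matches_classic_sobel(self):
        smooth, deriv = bd.sobel_kernels(3)
        np.testing.assert_array_equal(smooth, [1, 2, 1])
        np.testing.assert_array_equal(deriv, [1, 0, -1])

    def test_size5_matches_standard_extension(self):
        smooth, deriv = bd.sobel_kernels(5)
        np.testing.assert_array_equal(smooth, [1, 4, 6, 4, 1])
        np.testing.assert_array_equal(deriv, [1, 2, 0, -2, -1])

    def test_size3_agrees_with_skimage(self):
        from skimage.filters import sobel_h

        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (20, 20))
        field = bd.edge_index(img, mw.BoundaryParams(sobel_size=3))
        # skimage normalises the [1,2,1]x[1,0,-1] kernel by 4
        core = (slice(2, -2), slice(2, -2))
        np.testing.assert_allclose(field.s_h[core], sobel_h(img)[core] * 4,
                                   atol=1e-10)


class TestEdgeIndex:
    def test_constant_frame_gives_zero_field(self):
        field = bd.edge_index(np.full((12, 12), 9.0))
        np.testing.assert_allclose(field.values, 0.0, atol=1e-9)

    def test_horizontal_edge_has_no_vertical_component(self):
        frame = np.tile(np.linspace(0, 100, 16)[:, None], (1, 16))
        field = bd.edge_index(frame)
        np.testing.assert_allclose(field.s_v, 0.0, atol=1e-9)
        np.testing.assert_allclose(field.values, field.s_h, atol=1e-9)

    def test_vertical_edge_weighted_double(self):
        frame = np.tile(np.linspace(0, 100, 16)[None, :], (16, 1))
        field = bd.edge_index(frame)
        np.testing.assert_allclose(field.s_h, 0.0, atol=1e-9)
        np.testing.assert_allclose(field.values, 2 * field.s_v, atol=1e-9)

    def test_frame_smaller_than_aperture_rejected(self):
        with pytest.raises(FrameSizeError):
            bd.edge_index(np.zeros((4, 40)))


def _band_frame(height=100, width=60, top=40, bottom=60, value=200.0):
    frame = np.zeros((height, width))
    frame[top : bottom + 1] = value
    return frame


class TestDetectBoundaries:
    def test_bright_band_located(self):
        field = bd.edge_index(_band_frame())
        upper, lower, valid = bd.detect_boundaries(field)
        assert valid.all()
        assert np.all(np.abs(upper - 40) <= 2)
        assert np.all(np.abs(lower - 60) <= 2)

    def test_all_zero_field_all_invalid(self):
        field = bd.EdgeIndexField(values=np.zeros((30, 20)),
                                  s_h=np.zeros((30, 20)), s_v=np.zeros((30, 20)))
        _, _, valid = bd.detect_boundaries(field)
        assert not valid.any()

    def test_vertical_flip_equivariance(self, clean_sim):
        stack, _ = clean_sim
        params = mw.BoundaryParams()
        frame = mw.smooth_stack(stack, params).frames[3]
        u, l, v = bd.detect_boundaries(bd.edge_index(frame, params), params)
        uf, lf, vf = bd.detect_boundaries(bd.edge_index(frame[::-1], params), params)
        h = frame.shape[0]
        assert (v == vf).all()
        np.testing.assert_allclose(uf[v], (h - 1 - l)[v], atol=1e-9)
        np.testing.assert_allclose(lf[v], (h - 1 - u)[v], atol=1e-9)

    def test_intensity_scale_invariance(self, clean_sim):
        stack, _ = clean_sim
        params = mw.BoundaryParams()
        frame = mw.smooth_stack(stack, params).frames[3]
        u1, l1, v1 = bd.detect_boundaries(bd.edge_index(frame, params), params)
        u2, l2, v2 = bd.detect_boundaries(bd.edge_index(frame * 0.37, params), params)
        both = v1 & v2
        assert np.nanmax(np.abs(u1[both] - u2[both])) <= 0.5
        assert np.nanmax(np.abs(l1[both] - l2[both])) <= 0.5


class TestSmoothBoundaries:
    def test_linear_boundaries_reproduced(self):
        nc = 80
        cols = np.arange(nc, dtype=float)
        upper = 10 + 0.1 * cols
        lower = 50 + 0.05 * cols
        valid = np.ones(nc, dtype=bool)
        b = bd.smooth_boundaries(upper, lower, valid)
        np.testing.assert_allclose(b.upper[0], upper, atol=1e-6)
        np.testing.assert_allclose(b.lower[0], lower, atol=1e-6)

    def test_constant_boundaries_stay_constant(self):
        nc = 60
        b = bd.smooth_boundaries(np.full(nc, 20.0), np.full(nc, 70.0),
                                 np.ones(nc, dtype=bool))
        np.testing.assert_allclose(b.upper[0], 20.0, atol=1e-8)

    def test_single_column_spike_suppressed(self):
        nc = 80
        upper = np.full(nc, 30.0)
        upper[37] += 30.0  # glitch between knots
        b = bd.smooth_boundaries(upper, np.full(nc, 70.0), np.ones(nc, dtype=bool))
        assert abs(b.upper[0, 37] - 30.0) < 3.0

    def test_too_few_knots_flags_frame_unusable(self):
        nc = 15  # only 3 knots at spacing 10
        valid = np.ones(nc, dtype=bool)
        b = bd.smooth_boundaries(np.full(nc, 10.0), np.full(nc, 20.0), valid)
        assert not b.valid.any()

    def test_crossing_clamped_to_midpoint(self):
        nc = 80
        rng = np.random.default_rng(0)
        upper = np.full(nc, 40.0) + rng.normal(0, 0.1, nc)
        lower = np.full(nc, 40.5) + rng.normal(0, 0.1, nc)
        b = bd.smooth_boundaries(upper, lower, np.ones(nc, dtype=bool))
        v = b.valid[0]
        assert np.all(b.upper[0, v] < b.lower[0, v])


class TestPipelineAccuracy:
    def test_noise_free_mae_within_two_px(self, clean_sim, clean_boundaries):
        stack, gt = clean_sim
        assert boundary_mae(stack, gt, clean_boundaries) <= 2.0

    def test_noisy_mae_within_four_px(self, noisy_sim):
        stack, gt = noisy_sim
        b = mw.find_boundaries(stack)
        assert boundary_mae(stack, gt, b) <= 4.0

    def test_isolated_stain_blob_rejected_by_interpolation(self):
        # bright band rows 40-60 plus a compact blob far below it: the
        # blob hijacks the raw bottom-up crossing in its columns, but the
        # robust spline discards those columns and bridges across
        h, w = 120, 200
        ys, xs = np.mgrid[0:h, 0:w]
        band = np.where((ys >= 40) & (ys <= 60), 200.0, 0.0)
        blob = 220.0 * np.exp(-((xs - 120) ** 2 + (ys - 95) ** 2) / (2 * 2.5**2))
        clean = mw.FrameStack(np.broadcast_to(band, (4, h, w)).copy(), 0.2)
        stained = mw.FrameStack(np.clip(band + blob, 0, 255)[None].repeat(4, 0), 0.2)
        b0 = mw.find_boundaries(clean)
        b1 = mw.find_boundaries(stained)
        both = b0.valid & b1.valid
        assert both.mean() > 0.9
        assert np.nanmean(np.abs(b0.upper[both] - b1.upper[both])) < 0.5
        assert np.nanmean(np.abs(b0.lower[both] - b1.lower[both])) < 0.5

    def test_params_validation(self):
        with pytest.raises(ValidationError):
            mw.BoundaryParams(sobel_size=4)
        with pytest.raises(ValidationError):
            mw.BoundaryParams(threshold=0)
        with pytest.raises(ValidationError):
            mw.BoundaryParams(knot_spacing=1)
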