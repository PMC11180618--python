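"""Video and table IO: round-trips, validation, crop geometry."""

import numpy as np
import pytest

import myowave as mw
from myowave import video_io
from myowave.errors import (
    BoundsError,
    TableFormatError,
    ValidationError,
)


@pytest.fixture()
def tiny_stack() -> mw.FrameStack:
    rng = np.random.default_rng(0)
    frames = rng.integers(0, 256, size=(10, 64, 256)).astype(np.uint8)
    return mw.FrameStack(frames=frames, frame_interval=0.2)


class TestFrameStack:
    def test_shape_accessors(self, tiny_stack):
        assert (tiny_stack.n_frames, tiny_stack.height, tiny_stack.width) == (10, 64, 256)
        assert tiny_stack.fps == pytest.approx(5.0)

    @pytest.mark.parametrize(
        "frames, interval",
        [
            (np.zeros((1, 8, 8)), 0.2),     # single frame
            (np.zeros((3, 8, 8)), 0.0),     # bad interval
            (np.full((3, 8, 8), 300.0), 0.2),  # out of bit range
            (np.zeros((8, 8)), 0.2),        # not a stack
        ],
    )
    def test_invariant_violations(self, frames, interval):
        with pytest.raises(ValidationError):
            mw.FrameStack(frames=frames, frame_interval=interval)


class TestLoadSave:
    def test_tiff_round_trip_is_lossless(self, tiny_stack, tmp_path):
        path = video_io.save_video(tiny_stack, tmp_path / "clip.tif")
        back = mw.load_video(path, expected_interval=0.2)
        assert back.n_frames == 10 and back.height == 64 and back.width == 256
        assert np.array_equal(back.frames, tiny_stack.frames)

    def test_png_sequence_round_trip(self, tiny_stack, tmp_path):
        path = video_io.save_video(tiny_stack, tmp_path / "seq")
        back = mw.load_video(path, expected_interval=0.2)
        assert np.array_equal(back.frames, tiny_stack.frames)

    def test_simulator_round_trip(self, clean_sim, tmp_path):
        stack, _ = clean_sim
        back = mw.load_video(video_io.save_video(stack, tmp_path / "sim.tif"),
                             expected_interval=stack.frame_interval)
        assert np.max(np.abs(back.frames.astype(int) - stack.frames.astype(int))) == 0

    def test_single_frame_file_rejected(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "one.tif", np.zeros((8, 8), dtype=np.uint8))
        with pytest.raises(ValidationError, match="single frame"):
            mw.load_video(tmp_path / "one.tif")

    def test_missing_path_is_decode_error(self, tmp_path):
        from myowave.errors import DecodeError

        with pytest.raises(DecodeError):
            mw.load_video(tmp_path / "nope.avi")

    def test_color_converted_to_luminance_with_warning(self, tmp_path):
        import tifffile

        rgb = np.zeros((3, 8, 8, 3), dtype=np.uint8)
        rgb[..., 0] = 100  # pure red
        tifffile.imwrite(tmp_path / "rgb.tif", rgb)
        with pytest.warns(UserWarning, match="luminance"):
            stack = mw.load_video(tmp_path / "rgb.tif", expected_interval=0.2)
        assert stack.frames.shape == (3, 8, 8)
        assert stack.frames[0, 0, 0] == pytest.approx(29.9)


class TestCrop:
    def test_full_frame_is_identity(self, tiny_stack):
        out = mw.crop(tiny_stack, (0, 64, 0, 256))
        assert np.array_equal(out.frames, tiny_stack.frames)

    def test_height_one_rejected(self, tiny_stack):
        with pytest.raises(BoundsError, match="two boundaries"):
            mw.crop(tiny_stack, (10, 11, 0, 256))

    @pytest.mark.parametrize("rect", [(0, 0, 0, 10), (0, 70, 0, 10), (-1, 5, 0, 10)])
    def test_bad_rect_rejected(self, tiny_stack, rect):
        with pytest.raises(BoundsError):
            mw.crop(tiny_stack, rect)

    def test_complement_pixel_counts_sum(self, tiny_stack):
        left = mw.crop(tiny_stack, (0, 64, 0, 100))
        right = mw.crop(tiny_stack, (0, 64, 100, 256))
        total = left.height * left.width + right.height * right.width
        assert total == tiny_stack.height * tiny_stack.width

    def test_crop_commutes_with_grayscale(self):
        rng = np.random.default_rng(1)
        rgb = rng.integers(0, 256, size=(4, 32, 48, 3)).astype(float)
        gray = video_io._to_gray(rgb)
        a = mw.crop(mw.FrameStack(np.clip(gray, 0, 255), 0.2), (5, 20, 10, 40)).frames
        b = video_io._to_gray(rgb[:, 5:20, 10:40, :])
        np.testing.assert_allclose(a, np.clip(b, 0, 255), atol=1e-9)


class TestTables:
    def test_map_round_trip_preserves_values_and_nan(self, tmp_path):
        values = np.arange(9, dtype=float).reshape(3, 3)
        values[0, 2] = np.nan
        m = mw.SpatioTemporalMap(values=values, quantity="area_px")
        video_io.write_map(m, tmp_path / "m.csv")
        back = video_io.read_map(tmp_path / "m.csv")
        np.testing.assert_array_equal(back.values, values)
        assert back.quantity == "area_px"
        assert back.mask[0, 2] and not back.mask[0, 0]

    def test_boundaries_round_trip(self, clean_boundaries, tmp_path):
        video_io.write_boundaries(clean_boundaries, tmp_path / "b.csv")
        back = video_io.read_boundaries(tmp_path / "b.csv")
        np.testing.assert_array_equal(back.valid, clean_boundaries.valid)
        v = clean_boundaries.valid
        np.testing.assert_allclose(back.upper[v], clean_boundaries.upper[v])
        np.testing.assert_allclose(back.lower[v], clean_boundaries.lower[v])

    def test_annotation_round_trip_with_optional_period(self, tmp_path):
        anns = [
            mw.WaveAnnotation(ridge=((1.0, 2.0), (30.5, 40.0)),
                              band_extent=(0.0, 21.5),
                              next_ridge_frame=77.5, map_id="m1"),
            mw.WaveAnnotation(ridge=((5.0, 0.0), (2.0, 9.0)),
                              band_extent=(1.0, 4.0), map_id="m1"),
        ]
        video_io.write_annotations(anns, tmp_path / "a.csv")
        back = video_io.read_annotations(tmp_path / "a.csv")
        assert back[0].next_ridge_frame == 77.5
        assert back[1].next_ridge_frame is None
        assert back[0].ridge == anns[0].ridge

    def test_missing_ridge_columns_named_in_error(self, tmp_path):
        (tmp_path / "bad.csv").write_text("map_id,band_c0,band_c1\nx,0,1\n")
        with pytest.raises(TableFormatError, match="ridge_c0"):
            video_io.read_annotations(tmp_path / "bad.csv")

    def test_metrics_round_trip(self, tmp_path):
        metrics = [mw.WaveMetrics(amplitude_um=189.4, velocity_um_s=12.8,
                                  direction="toward_cervix", period_s=62.5,
                                  frequency_hz=0.016, wavelength_um=800.0,
                                  segment="middle")]
        video_io.write_metrics(metrics, tmp_path / "w.csv")
        back = video_io.read_metrics(tmp_path / "w.csv")
        assert back[0].wavelength_um == pytest.approx(800.0)
        assert back[0].segment == "middle"
        assert back[0].direction == "toward_cervix"

    def test_sidecar_carries_calibration(self, tmp_path):
        m = mw.SpatioTemporalMap(values=np.ones((3, 3)), quantity="mean_intensity",
                                 calibration=mw.CalibrationConfig(fps=2.0))
        video_io.write_map(m, tmp_path / "m.csv")
        assert video_io.read_map(tmp_path / "m.csv").calibration.fps == 2.0
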