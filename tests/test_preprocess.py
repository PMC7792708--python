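"""Signal-conditioning stages and the fixed pipeline order."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import epimap as em
from epimap.io import MovieStack
from epimap.preprocess import (
    PixelMask,
    PreprocessConfig,
    Reason,
    apply_roi,
    detrend,
    exclude_bad_pixels,
    lowpass,
    normalize,
    preprocess_movie,
    spatial_mean_filter,
    subtract_background,
)

FR = 490.2


def _movie(frames, **meta):
    return MovieStack(np.asarray(frames, float), FR, 118.0, meta)


class TestApplyRoi:
    def test_full_frame_rectangle_includes_everything(self):
        mov = _movie(np.zeros((2, 8, 8)))
        mask = apply_roi(mov, [(-1, -1), (8, -1), (8, 8), (-1, 8)])
        assert mask.included.all()

    def test_degenerate_polygon_rejected(self):
        mov = _movie(np.zeros((2, 8, 8)))
        with pytest.raises(ValueError):
            apply_roi(mov, [(0, 0), (5, 5)])

    def test_triangle_matches_point_in_polygon_oracle(self):
        from shapely.geometry import Point, Polygon

        verts = [(-0.5, -0.5), (40.3, -0.5), (-0.5, 40.7)]
        mov = _movie(np.zeros((2, 64, 64)))
        mask = apply_roi(mov, verts)
        poly = Polygon(verts)
        oracle = np.zeros((64, 64), bool)
        for r in range(64):
            for c in range(64):
                oracle[r, c] = poly.contains(Point(c, r))
        assert np.array_equal(mask.included, oracle)
        assert (mask.reason[~mask.included] == Reason.OUT_OF_ROI).all()


class TestExcludeBadPixels:
    def test_saturated_and_constant_pixels_excluded(self):
        frames = np.random.default_rng(0).normal(100, 5, (50, 4, 4))
        frames[:, 1, 1] = 100.0  # zero variance
        frames[7, 2, 2] = 2000.0  # one saturated sample suffices
        mov = _movie(frames, saturation_level=2000.0)
        cfg = PreprocessConfig(variance_threshold=1.0)
        mask = exclude_bad_pixels(mov, PixelMask.full((4, 4)), cfg)
        assert not mask.included[1, 1] and mask.reason[1, 1] == Reason.LOW_VARIANCE
        assert not mask.included[2, 2] and mask.reason[2, 2] == Reason.SATURATED
        assert mask.included.sum() == 14

    def test_injected_dead_pixels_recovered(self):
        """≥99 % of a 5 % dead-pixel population is excluded at the adaptive
        variance threshold."""
        protocol = em.build_protocol([200.0], 6, FR)
        noise = em.NoiseModel(gaussian_sd=10.0, dead_pixel_fraction=0.05, seed=3)
        movie, _ = em.simulate_movie(protocol, noise=noise, grid=(32, 32))
        dead = {
            tuple(map(int, s.split(","))) for s in movie.meta["dead_pixels"].split(";")
        }
        mask = exclude_bad_pixels(movie, PixelMask.full((32, 32)), PreprocessConfig())
        found = {tuple(p) for p in np.argwhere(~mask.included)}
        assert len(dead & found) >= math.ceil(0.99 * len(dead))


class TestDetrend:
    def test_line_and_constant_map_to_zero(self):
        t = np.arange(100.0)
        assert np.allclose(detrend(3.0 + 0.5 * t), 0.0, atol=1e-9)
        assert np.allclose(detrend(np.full(100, 100.0)), 0.0, atol=1e-9)

    def test_ramp_plus_sinusoid_leaves_sinusoid(self):
        """Least-squares line on the summed trace (polyfit oracle) is what is
        removed; a full-period sinusoid survives nearly unchanged."""
        t = np.arange(200.0)
        sin = np.sin(2 * np.pi * t / 50.0)
        x = 2.0 + 0.3 * t + sin
        line = np.polyval(np.polyfit(t, x, 1), t)  # oracle
        out = detrend(x)
        assert np.allclose(out, x - line, atol=1e-9)
        # the ramp is gone entirely; the sinusoid survives with its amplitude
        assert np.allclose(out, detrend(sin), atol=1e-9)
        assert np.ptp(out) == pytest.approx(np.ptp(sin), rel=0.2)


class TestLowpass:
    @staticmethod
    def _digital_butter_gain(f, fc, order, fs):
        """Closed-form bilinear-transform Butterworth magnitude."""
        ratio = math.tan(math.pi * f / fs) / math.tan(math.pi * fc / fs)
        return 1.0 / math.sqrt(1.0 + ratio ** (2 * order))

    def test_dc_preserved(self):
        x = np.full(500, 7.0)
        assert np.allclose(lowpass(x, FR), 7.0, atol=1e-9)

    @pytest.mark.parametrize("freq,rtol", [(200.0, 0.02), (1.0, 0.01)])
    def test_sinusoid_gain_matches_closed_form(self, freq, rtol):
        t = np.arange(4000) / FR
        x = np.sin(2 * np.pi * freq * t)
        y = lowpass(x, FR, cutoff=40.0, order=4)
        mid = slice(1000, 3000)
        gain = np.sqrt(np.mean(y[mid] ** 2) / np.mean(x[mid] ** 2))
        expected = self._digital_butter_gain(freq, 40.0, 4, FR) ** 2  # fwd+bwd
        assert gain == pytest.approx(expected, rel=rtol, abs=1e-4)

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass(np.zeros(100), FR, cutoff=300.0)


class TestBackgroundAndNormalize:
    def test_flat_baseline_removed(self):
        x = np.full(200, 50.0)
        x[::20] = 150.0
        out = subtract_background(x)
        assert np.median(out) == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(subtract_background(np.zeros(100)), 0.0)

    def test_normalize_examples(self):
        assert np.allclose(normalize(np.array([0.0, 50.0, 100.0])), [1, 50.5, 100])
        with pytest.raises(ValueError):
            normalize(np.full(10, 3.0))

    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=50,
        ).filter(lambda v: max(v) > min(v))
    )
    @settings(max_examples=60, deadline=None)
    def test_normalize_hits_range_exactly_and_is_idempotent(self, vals):
        y = normalize(np.array(vals))
        assert y.min() == pytest.approx(1.0, abs=1e-9)
        assert y.max() == pytest.approx(100.0, abs=1e-9)
        assert np.allclose(normalize(y), y, atol=1e-9)


class TestSpatialMeanFilter:
    def test_uniform_frame_unchanged(self):
        mask = PixelMask.full((10, 10))
        frames = np.full((3, 10, 10), 4.2)
        assert np.allclose(spatial_mean_filter(frames, mask), 4.2)

    def test_interior_impulse_spreads_to_patch(self):
        mask = PixelMask.full((11, 11))
        frame = np.zeros((1, 11, 11))
        frame[0, 5, 5] = 25.0
        out = spatial_mean_filter(frame, mask)[0]
        assert np.allclose(out[3:8, 3:8], 1.0)
        assert out.sum() == pytest.approx(25.0)

    def test_masked_mean_matches_brute_force(self):
        rng = np.random.default_rng(11)
        frame = rng.normal(size=(1, 12, 12))
        inc = rng.random((12, 12)) > 0.3
        mask = PixelMask(inc, np.where(inc, 0, 4).astype(np.uint8))
        out = spatial_mean_filter(frame, mask)[0]
        for r in range(12):
            for c in range(12):
                if not inc[r, c]:
                    assert out[r, c] == frame[0, r, c]  # untouched
                    continue
                acc = [
                    frame[0, rr, cc]
                    for rr in range(max(r - 2, 0), min(r + 3, 12))
                    for cc in range(max(c - 2, 0), min(c + 3, 12))
                    if inc[rr, cc]
                ]
                assert out[r, c] == pytest.approx(np.mean(acc), abs=1e-12)


class TestPipeline:
    def test_stage_order_is_fixed(self, protocol_2pcl):
        """preprocess_movie equals the hand-chained stage sequence exactly."""
        movie, _ = em.simulate_movie(
            protocol_2pcl,
            noise=em.NoiseModel(gaussian_sd=5.0, drift_slope=10.0, seed=1),
            grid=(12, 12),
        )
        cond, mask = preprocess_movie(movie)
        t, h, w = movie.frames.shape
        manual_mask = exclude_bad_pixels(movie, PixelMask.full((h, w)), PreprocessConfig())
        traces = movie.frames.reshape(t, h * w).T
        traces = detrend(traces)
        traces = lowpass(traces, FR, 40.0, 4)
        traces = subtract_background(traces, 5.0)
        traces = normalize(traces)
        manual = spatial_mean_filter(traces.T.reshape(t, h, w), manual_mask)
        assert np.array_equal(mask.included, manual_mask.included)
        assert np.allclose(cond.frames, manual, atol=1e-12)

    def test_pixel_count_conserved_and_monotone(self, protocol_2pcl):
        movie, _ = em.simulate_movie(
            protocol_2pcl,
            noise=em.NoiseModel(gaussian_sd=5.0, dead_pixel_fraction=0.1, seed=2),
            grid=(16, 16),
        )
        roi = [(1.5, 1.5), (14.5, 1.5), (14.5, 14.5), (1.5, 14.5)]
        roi_mask = apply_roi(movie, roi)
        _, final = preprocess_movie(movie, roi_polygon=roi)
        h, w = movie.grid
        assert final.n_included + (~final.included).sum() == h * w
        # exclusion only grows, and each excluded pixel has one primary reason
        assert not (final.included & ~roi_mask.included).any()
        assert (final.reason[~final.included] != Reason.INCLUDED).all()
        assert (final.reason[final.included] == Reason.INCLUDED).all()
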