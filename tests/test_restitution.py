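"""Restitution points, monoexponential fits, and vector angles."""

import numpy as np
import pytest

import epimap as em
from epimap.beats import PclMaps
from epimap.restitution import (
    RestitutionPoint,
    fit_monoexponential,
    global_restitution_points,
    per_pixel_vector_angle_map,
    restitution_vector_angle,
    two_stage_group_fit,
)


def _maps(pcl, apd, di, shape=(4, 4)):
    return PclMaps(
        pcl=pcl,
        apd60_mean=np.full(shape, apd, float),
        di_mean=np.full(shape, di, float),
        beats_used=np.full(shape, 4, np.uint8),
    )


def eq1(di, a, b, tau):
    return a * (1.0 - b * np.exp(-np.asarray(di, float) / tau))


class TestGlobalPoints:
    def test_uniform_maps_give_their_value(self):
        pts = global_restitution_points({150.0: _maps(150.0, 55.0, 95.0)})
        assert len(pts) == 1
        assert (pts[0].apd60_ms, pts[0].di_ms) == (55.0, 95.0)
        assert pts[0].n_pixels == 16

    def test_single_pixel_map_equals_that_pixel(self):
        pts = global_restitution_points({250.0: _maps(250.0, 60.0, 190.0, (1, 1))})
        assert pts[0].apd60_ms == 60.0 and pts[0].n_pixels == 1

    def test_undefined_pcl_omitted(self):
        empty = _maps(97.0, np.nan, np.nan)
        pts = global_restitution_points({97.0: empty, 150.0: _maps(150.0, 55.0, 95.0)})
        assert [p.pcl for p in pts] == [150.0]

    def test_points_satisfy_pcl_identity_on_generated_data(self):
        """Per-pixel maps built from full-scale ground truth satisfy
        APD + DI = PCL to 1e-6 ms, so do the global points."""
        protocol = em.build_protocol([250.0, 150.0], 30, 490.2)
        _, gt = em.simulate_movie(
            protocol, em.APModel(), em.WavePattern(speed=50.0), grid=(8, 8)
        )
        for pcl, s4, s_di in [(250.0, slice(26, 30), slice(25, 29)),
                              (150.0, slice(56, 60), slice(55, 59))]:
            maps = PclMaps(
                pcl=pcl,
                apd60_mean=np.nanmean(gt.apd60_ms[s4], axis=0),
                di_mean=np.nanmean(gt.di_ms[s_di], axis=0),
                beats_used=np.full((8, 8), 4, np.uint8),
            )
            (pt,) = global_restitution_points({pcl: maps})
            assert pt.apd60_ms + pt.di_ms == pytest.approx(pcl, abs=1e-6)
            ident = maps.apd60_mean + maps.di_mean - pcl
            assert np.nanmax(np.abs(ident)) < 1e-6


class TestFitMonoexponential:
    def test_exact_points_recovered_to_1e6(self):
        dis = [30.0, 60.0, 90.0, 150.0, 200.0]
        pts = [(d, eq1(d, 70.0, 0.6, 40.0)) for d in dis]
        fit = fit_monoexponential(pts)
        assert fit.apd_ss == pytest.approx(70.0, rel=1e-6)
        assert fit.b == pytest.approx(0.6, rel=1e-6)
        assert fit.tau == pytest.approx(40.0, rel=1e-6)

    def test_fixed_b_zero_gives_mean_apd(self):
        pts = [(50.0, 54.0), (100.0, 56.0), (200.0, 58.0)]
        fit = fit_monoexponential(pts, fixed_b_tau=(0.0, 40.0))
        assert fit.apd_ss == pytest.approx(np.mean([54, 56, 58]))

    def test_curve_asymptotes_to_apd_ss(self):
        fit = em.RestitutionFit(apd_ss=70.0, b=0.6, tau=40.0, residual_norm=0.0)
        assert fit.curve(np.array([1e6]))[0] == pytest.approx(70.0)

    def test_curve_monotone_in_di(self):
        fit = em.RestitutionFit(apd_ss=70.0, b=0.6, tau=40.0, residual_norm=0.0)
        di = np.linspace(1.0, 400.0, 500)
        assert (np.diff(fit.curve(di)) > 0).all()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_monoexponential([(50.0, 55.0), (90.0, 60.0)])


class TestTwoStageGroupFit:
    @staticmethod
    def _heart_points(apd_ss, b=0.6, tau=40.0, pcls=(250, 200, 175, 150, 125, 97)):
        pts = []
        for pcl in pcls:
            apd = em.steady_state_apd(pcl, apd_ss, b, tau)
            pts.append((pcl - apd, apd))
        return pts

    def test_single_heart_group_equals_group_fit(self):
        pts = self._heart_points(65.0)
        group, per_heart = two_stage_group_fit({"h1": pts})
        assert per_heart["h1"].apd_ss == pytest.approx(group.apd_ss, rel=1e-9)

    def test_identical_hearts_share_apd_ss(self):
        pts = self._heart_points(70.0)
        group, per_heart = two_stage_group_fit({"a": pts, "b": list(pts)})
        assert per_heart["a"].apd_ss == pytest.approx(per_heart["b"].apd_ss)
        assert per_heart["a"].apd_ss == pytest.approx(group.apd_ss, rel=1e-9)

    def test_noise_free_recovery_under_1ms_rmse(self):
        rng = np.random.default_rng(0)
        truth = rng.uniform(60.0, 80.0, 5)
        hearts = {f"h{i}": self._heart_points(a) for i, a in enumerate(truth)}
        _, per_heart = two_stage_group_fit(hearts)
        est = np.array([per_heart[f"h{i}"].apd_ss for i in range(5)])
        assert np.sqrt(np.mean((est - truth) ** 2)) < 1.0

    def test_stage2_matches_dense_grid_search(self):
        """Closed-form APD_ss-only fit equals a 1e-4-resolution grid search
        on 20 random fixtures."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            b = rng.uniform(0.1, 0.9)
            tau = rng.uniform(20.0, 80.0)
            di = rng.uniform(20.0, 250.0, 6)
            apd = eq1(di, rng.uniform(55.0, 85.0), b, tau) + rng.normal(0, 1.0, 6)
            fit = fit_monoexponential(list(zip(di, apd)), fixed_b_tau=(b, tau))
            s = 1.0 - b * np.exp(-di / tau)
            grid = np.arange(1e-4, 2.0 * apd.max(), 1e-4)
            sse = (
                np.sum(apd**2)
                - 2.0 * grid * np.dot(apd, s)
                + grid**2 * np.dot(s, s)
            )
            best = grid[np.argmin(sse)]
            assert fit.apd_ss == pytest.approx(best, abs=1e-4)

    def test_noise_bias_below_half_ms(self):
        """1 ms APD noise, 200 Monte-Carlo replicates: APD_ss recovery bias
        stays below 0.5 ms."""
        rng = np.random.default_rng(12)
        truth = rng.uniform(60.0, 80.0, 5)
        clean = {f"h{i}": self._heart_points(a) for i, a in enumerate(truth)}
        errs = []
        for _ in range(200):
            noisy = {
                h: [(di, apd + rng.normal(0, 1.0)) for di, apd in pts]
                for h, pts in clean.items()
            }
            _, per_heart = two_stage_group_fit(noisy)
            for i in range(5):
                errs.append(per_heart[f"h{i}"].apd_ss - truth[i])
        assert abs(np.mean(errs)) < 0.5


class TestVectorAngle:
    @pytest.mark.parametrize(
        "delta,expected",
        [((-25.0, 0.0), 180.0), ((0.0, -5.0), 270.0), ((-10.0, 2.0), 168.69)],
    )
    def test_angle_examples(self, delta, expected):
        p175 = RestitutionPoint(175.0, apd60_ms=55.0, di_ms=120.0)
        p150 = RestitutionPoint(
            150.0, apd60_ms=55.0 + delta[1], di_ms=120.0 + delta[0]
        )
        assert restitution_vector_angle(p175, p150) == pytest.approx(expected, abs=0.01)

    def test_identical_points_undefined(self):
        p = RestitutionPoint(175.0, 55.0, 120.0)
        with pytest.raises(ValueError):
            restitution_vector_angle(p, RestitutionPoint(150.0, 55.0, 120.0))

    def test_uniform_maps_reproduce_global_angle(self):
        m175 = _maps(175.0, 57.0, 118.0)
        m150 = _maps(150.0, 55.5, 94.5)
        amap = per_pixel_vector_angle_map(m175, m150)
        g = restitution_vector_angle(
            global_restitution_points({175.0: m175})[0],
            global_restitution_points({150.0: m150})[0],
        )
        assert np.allclose(amap, g)

    def test_pixel_missing_at_either_pcl_is_undefined(self):
        m175 = _maps(175.0, 57.0, 118.0)
        m150 = _maps(150.0, 55.5, 94.5)
        m150.apd60_mean[1, 1] = np.nan
        amap = per_pixel_vector_angle_map(m175, m150)
        assert np.isnan(amap[1, 1]) and np.isfinite(amap[0, 0])

    def test_two_region_field_segregates_into_two_modes(self):
        """A planted two-region APD_ss field yields an angle map with exactly
        the two planted transition angles."""
        m175 = _maps(175.0, 55.0, 120.0, (8, 8))
        m150 = _maps(150.0, 54.0, 96.0, (8, 8))
        m175.apd60_mean[:, 4:] = 60.0
        m150.apd60_mean[:, 4:] = 50.0
        m150.di_mean[:, 4:] = 100.0
        amap = per_pixel_vector_angle_map(m175, m150)
        left = np.degrees(np.arctan2(-1.0, -24.0)) % 360  # planted region A
        right = np.degrees(np.arctan2(-10.0, -20.0)) % 360  # planted region B
        assert np.allclose(amap[:, :4], left)
        assert np.allclose(amap[:, 4:], right)
        assert len(np.unique(np.round(amap, 6))) == 2
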