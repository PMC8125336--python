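"""Sway parameters, load-absorption RMS and the 13-feature vector."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from aclrisk.features import (
    FEATURE_NAMES,
    StabilityParams,
    build_feature_vector,
    ellipse_area,
    ellipse_params,
    normalize_stability,
    path_lengths,
    rms_load,
)
from aclrisk.orientation import GRAVITY, IMUTrial, SwayPath

FS = 100.0


def _path(xy):
    xy = np.asarray(xy, dtype=float)
    return SwayPath(np.arange(len(xy)) / FS, xy)


class TestPathLengths:
    def test_unit_square_hand_sum(self):
        pl, pl_ap, pl_ml = path_lengths(_path([(0, 0), (1, 0), (1, 1), (0, 1)]))
        assert (pl, pl_ap, pl_ml) == (3.0, 1.0, 2.0)

    def test_constant_path_is_zero(self):
        assert path_lengths(_path([(2, 3)] * 10)) == (0.0, 0.0, 0.0)

    def test_matches_bruteforce_on_random_path(self, rng):
        xy = rng.standard_normal((1000, 2))
        pl, pl_ap, pl_ml = path_lengths(_path(xy))
        # independent per-segment re-summation
        exp_pl = exp_ap = exp_ml = 0.0
        for a, b in zip(xy[:-1], xy[1:]):
            exp_pl += float(np.sqrt((b[0] - a[0]) ** 2 + (b[1] - a[1]) ** 2))
            exp_ml += abs(b[0] - a[0])
            exp_ap += abs(b[1] - a[1])
        assert pl == pytest.approx(exp_pl, rel=1e-12)
        assert pl_ap == pytest.approx(exp_ap, rel=1e-12)
        assert pl_ml == pytest.approx(exp_ml, rel=1e-12)

    def test_single_sample_raises(self):
        with pytest.raises(ValueError, match="2 samples"):
            path_lengths(_path([(0, 0)]))

    @given(st.integers(0, 2**32 - 1))
    def test_triangle_inequalities(self, seed):
        xy = np.random.default_rng(seed).standard_normal((50, 2))
        pl, pl_ap, pl_ml = path_lengths(_path(xy))
        assert pl >= max(pl_ap, pl_ml) - 1e-12
        assert pl <= pl_ap + pl_ml + 1e-12


class TestEllipseArea:
    def test_isotropic_cloud_reduces_to_formula(self, rng):
        xy = rng.standard_normal((500, 2)) * 2.0
        # enforce exactly isotropic, uncorrelated sample moments
        xy = (xy - xy.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(xy.T))).T
        xy *= 2.0
        ea = ellipse_area(xy)
        f = stats.f.ppf(0.99, 2, len(xy) - 2)
        assert ea == pytest.approx(2 * np.pi * f * 4.0, rel=1e-9)

    def test_coverage_close_to_nominal(self, rng):
        xy = rng.multivariate_normal([0, 0], [[2.0, 0.7], [0.7, 1.0]], size=10_000)
        centre, cov, r2 = ellipse_params(xy)
        d = xy - centre
        m2 = np.einsum("ij,jk,ik->i", d, np.linalg.inv(cov), d)
        assert np.mean(m2 <= r2) >= 0.98

    def test_affine_stretch_doubles_area(self, rng):
        xy = rng.standard_normal((200, 2))
        stretched = xy * np.array([2.0, 1.0])
        assert ellipse_area(stretched) == pytest.approx(2 * ellipse_area(xy), rel=1e-9)

    def test_translation_invariance(self, rng):
        xy = rng.standard_normal((100, 2))
        assert ellipse_area(xy + [50.0, -3.0]) == pytest.approx(
            ellipse_area(xy), rel=1e-12
        )

    def test_isotropic_scaling_quadratic(self, rng):
        xy = rng.standard_normal((100, 2))
        assert ellipse_area(3.0 * xy) == pytest.approx(9 * ellipse_area(xy), rel=1e-9)

    def test_collinear_cloud_warns_and_returns_zero(self):
        xy = np.column_stack([np.linspace(0, 1, 30), np.linspace(0, 2, 30)])
        with pytest.warns(UserWarning, match="collinear"):
            assert ellipse_area(xy) == 0.0


class TestRmsLoad:
    def _trial(self, accel):
        t = np.arange(len(accel)) / FS
        return IMUTrial(t, accel, np.zeros((len(accel), 3)))

    def test_pure_gravity_gives_zero(self):
        tr = self._trial(np.tile([0, 0, GRAVITY], (100, 1)))
        load = rms_load(tr, None, 0.0, 0.5)
        assert load.RMS_z == pytest.approx(0.0, abs=1e-12)
        assert load.RMS_xy == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_normalized_by_ts(self):
        tr = self._trial(np.tile([0, 0, GRAVITY + 2.0], (100, 1)))
        load = rms_load(tr, None, 0.0, 0.5)
        assert load.RMS_z == pytest.approx(4.0)  # 2 m/s^2 RMS / 0.5 s

    def test_empty_window_raises(self):
        tr = self._trial(np.tile([0, 0, GRAVITY], (100, 1)))
        with pytest.raises(ValueError, match="window"):
            rms_load(tr, None, 5.0, 0.5)


class TestNormalizeStability:
    def test_divides_every_field(self):
        p = normalize_stability(StabilityParams(2.0, 1.0, 0.5, 1.0), 2.0)
        assert (p.PL, p.PL_AP, p.PL_ML, p.EA) == (1.0, 0.5, 0.25, 0.5)

    def test_unit_duration_is_identity(self):
        p = StabilityParams(2.0, 1.0, 0.5, 1.0)
        assert normalize_stability(p, 1.0) == p

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_duration_raises(self, bad):
        with pytest.raises(ValueError, match="positive"):
            normalize_stability(StabilityParams(1, 1, 1, 1), bad)


class TestFeatureVector:
    def _rep(self, value, keys):
        return {k: value for k in keys}

    def test_identical_reps_pass_through(self):
        mcmj = [self._rep(2.0, FEATURE_NAMES[:7])] * 5
        sls = [self._rep(3.0, FEATURE_NAMES[7:])] * 5
        fv = build_feature_vector(mcmj, sls, "A1")
        assert np.allclose(fv.values[:7], 2.0)
        assert np.allclose(fv.values[7:], 3.0)

    def test_mean_across_reps(self):
        mcmj = [self._rep(v, FEATURE_NAMES[:7]) for v in (1, 2, 3, 4, 5)]
        sls = [self._rep(0.0, FEATURE_NAMES[7:])] * 5
        fv = build_feature_vector(mcmj, sls)
        assert np.allclose(fv.values[:7], 3.0)

    def test_zero_reps_raises(self):
        with pytest.raises(ValueError, match="no mCMJ"):
            build_feature_vector([], [self._rep(0.0, FEATURE_NAMES[7:])] * 5)

    def test_fewer_reps_warns_when_allowed(self):
        mcmj = [self._rep(1.0, FEATURE_NAMES[:7])] * 3
        sls = [self._rep(1.0, FEATURE_NAMES[7:])] * 5
        with pytest.raises(ValueError, match="expected 5"):
            build_feature_vector(mcmj, sls)
        with pytest.warns(UserWarning, match="3 < 5"):
            build_feature_vector(mcmj, sls, allow_fewer=True)


class TestWindowing:
    def test_stability_params_use_only_window_samples(self):
        """Points outside [t0, t1] must not leak into the sway measures."""
        inside = np.array([(0, 0), (1, 0), (1, 1), (0, 1)], dtype=float)
        wild = 100 * np.ones((10, 2))
        xy = np.vstack([wild, inside, wild])
        path = SwayPath(np.arange(len(xy)) / FS, xy)
        window = (10 / FS, 13 / FS)
        assert path_lengths(path, window) == (3.0, 1.0, 2.0)
        ea_win = ellipse_area(path, window)
        assert ea_win == pytest.approx(ellipse_area(inside))
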