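"""Fuzzy c-means core: update rules, constraints, defuzzification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from liverfcm import (
    DegenerateClusteringError,
    DegenerateFeatureError,
    FCMParams,
    InputError,
    MultiEchoStack,
    ScalarMap,
    build_features,
    defuzzify,
    fcm_cluster,
    identify_vessel_cluster,
)
from liverfcm.fcm import FeatureMatrix
from tests.conftest import TE20


def brute_force_fcm(x, c=2, m=2.0, tol=1e-12, max_iter=2000):
    """Independent reference: plain-loop fixed-point iteration of the
    membership/centroid update equations, run to tight tolerance."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, k = x.shape
    v = np.stack([np.percentile(x, 10, axis=0), np.percentile(x, 90, axis=0)])
    for _ in range(max_iter):
        u = np.zeros((c, n))
        for j in range(n):
            d2 = [max(np.sum((x[j] - v[i]) ** 2), 1e-30) for i in range(c)]
            for i in range(c):
                u[i, j] = 1.0 / sum((d2[i] / d2[l]) ** (1.0 / (m - 1.0))
                                    for l in range(c))
        v_new = np.zeros_like(v)
        for i in range(c):
            w = u[i] ** m
            v_new[i] = (w[:, None] * x).sum(axis=0) / w.sum()
        if np.abs(v_new - v).max() < tol:
            return v_new, u
        v = v_new
    return v, u


def features_1d(values):
    values = np.asarray(values, dtype=float)
    return FeatureMatrix(x=values[None, :], pixel_index=np.arange(len(values)),
                         mode="1D", te_index=0, shape=(1, len(values)))


class TestClusterUpdates:
    def test_symmetric_two_group_data(self):
        res = fcm_cluster(features_1d([0.0, 0.01, 0.99, 1.0]))
        assert res.converged
        v = np.sort(res.centroids[:, 0])
        assert v[0] + v[1] == pytest.approx(1.0, abs=1e-6)
        assert v[0] == pytest.approx(0.005, abs=0.02)
        assert v[1] == pytest.approx(0.995, abs=0.02)

    def test_memberships_sum_to_one(self):
        rng = np.random.default_rng(0)
        res = fcm_cluster(features_1d(rng.random(60)))
        assert np.allclose(res.memberships.sum(axis=0), 1.0, atol=1e-9)
        assert res.memberships.min() >= 0 and res.memberships.max() <= 1

    def test_objective_nonincreasing(self):
        rng = np.random.default_rng(1)
        res = fcm_cluster(features_1d(rng.random(80)))
        assert np.all(np.diff(res.objective_trace) <= 1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=4, max_size=20))
    def test_matches_brute_force_oracle(self, values):
        """Converged centroids agree with an independent plain-loop
        fixed-point iteration run to 1e-12."""
        values = np.asarray(values)
        if np.ptp(values) < 1e-3:  # degenerate one-blob data: skip
            return
        res = fcm_cluster(features_1d(values), FCMParams(tol=1e-10, max_iter=2000))
        v_ref, _ = brute_force_fcm(values)
        assert np.allclose(np.sort(res.centroids[:, 0]),
                           np.sort(v_ref[:, 0]), atol=1e-6)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        values = rng.random(40)
        perm = rng.permutation(40)
        res = fcm_cluster(features_1d(values))
        res_p = fcm_cluster(features_1d(values[perm]))
        assert np.allclose(res.memberships[:, perm], res_p.memberships, atol=1e-6)

    def test_point_on_centroid_gets_crisp_membership(self):
        # two exact point-masses: centroids land on them, memberships crisp
        res = fcm_cluster(features_1d([0.0, 0.0, 0.0, 1.0, 1.0, 1.0]))
        assert np.all(res.memberships.max(axis=0) > 0.999)

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        values = rng.random(50)
        a = fcm_cluster(features_1d(values))
        b = fcm_cluster(features_1d(values))
        assert np.array_equal(a.memberships, b.memberships)
        assert np.array_equal(a.centroids, b.centroids)

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            fcm_cluster(features_1d([0.5]))

    def test_params_validated(self):
        with pytest.raises(InputError):
            FCMParams(m=1.0)
        with pytest.raises(InputError):
            FCMParams(tol=0.0)


class TestBuildFeatures:
    def _stack(self, rng):
        echoes = rng.uniform(1, 100, (20, 6, 6))
        return MultiEchoStack(echoes=echoes, te_ms=TE20)

    def test_2d_features_span_unit_interval(self):
        rng = np.random.default_rng(0)
        stack = self._stack(rng)
        roi = np.zeros((6, 6), dtype=bool)
        roi.ravel()[:10] = True
        lic = ScalarMap(values=rng.uniform(1, 20, (6, 6)), valid_mask=np.ones((6, 6), bool))
        f = build_features(stack, lic, roi, "2D", 4)
        assert f.x.shape == (2, 10)
        for row in f.x:
            assert row.min() == pytest.approx(0.0)
            assert row.max() == pytest.approx(1.0)

    def test_1d_is_normalized_echo(self):
        rng = np.random.default_rng(1)
        stack = self._stack(rng)
        roi = np.ones((6, 6), dtype=bool)
        f = build_features(stack, None, roi, "1D", 7)
        img = stack.echoes[7].ravel()
        expected = (img - img.min()) / np.ptp(img)
        assert np.allclose(f.x[0], expected)

    def test_invalid_lic_pixels_excluded_and_recorded(self):
        rng = np.random.default_rng(2)
        stack = self._stack(rng)
        roi = np.ones((6, 6), dtype=bool)
        valid = np.ones((6, 6), bool)
        valid.ravel()[[3, 17, 30]] = False
        lic = ScalarMap(values=rng.uniform(1, 20, (6, 6)), valid_mask=valid)
        f = build_features(stack, lic, roi, "2D", 0)
        assert f.n == 33
        assert sorted(f.excluded_index) == [3, 17, 30]

    def test_constant_feature_rejected(self):
        stack = MultiEchoStack(echoes=np.ones((20, 4, 4)), te_ms=TE20)
        with pytest.raises(DegenerateFeatureError):
            build_features(stack, None, np.ones((4, 4), bool), "1D", 0)


class TestVesselClusterIdentification:
    def _result(self, centroids):
        from liverfcm.fcm import FCMResult
        return FCMResult(memberships=np.ones((2, 4)) / 2, centroids=np.asarray(centroids),
                         objective_trace=np.array([1.0]), iterations=1, converged=True)

    def test_2d_vessel_is_low_lic_centroid(self):
        f = FeatureMatrix(x=np.zeros((2, 4)), pixel_index=np.arange(4), mode="2D",
                          te_index=0, shape=(2, 2))
        res = self._result([[0.5, 0.8], [0.5, 0.2]])
        assert identify_vessel_cluster(res, f) == 1

    def test_1d_vessel_is_bright_centroid(self):
        f = features_1d([0.0, 1.0, 0.5, 0.2])
        res = self._result([[0.3], [0.7]])
        assert identify_vessel_cluster(res, f) == 1

    def test_identical_centroids_degenerate(self):
        f = features_1d([0.0, 1.0, 0.5, 0.2])
        res = self._result([[0.5], [0.5]])
        with pytest.raises(DegenerateClusteringError):
            identify_vessel_cluster(res, f)


class TestDefuzzify:
    def _setup(self, memberships):
        from liverfcm.fcm import FCMResult
        n = len(memberships)
        u = np.stack([np.asarray(memberships), 1 - np.asarray(memberships)])
        res = FCMResult(memberships=u, centroids=np.array([[1.0], [0.0]]),
                        objective_trace=np.array([1.0]), iterations=1, converged=True)
        f = features_1d(np.linspace(0, 1, n))
        roi = np.ones((1, n), dtype=bool)
        return res, f, roi

    def test_threshold_rule(self):
        res, f, roi = self._setup([0.9, 0.6, 0.3])
        mask = defuzzify(res, 0, 0.5, roi, f)
        assert list(mask.vessel.ravel()) == [True, True, False]
        assert list(mask.parenchyma.ravel()) == [False, False, True]

    def test_zero_threshold_labels_everything_vessel(self):
        res, f, roi = self._setup([0.9, 0.6, 0.3])
        assert defuzzify(res, 0, 0.0, roi, f).vessel.all()

    def test_max_threshold_above_all_memberships_empty(self):
        res, f, roi = self._setup([0.9, 0.6, 0.3])
        assert not defuzzify(res, 0, 0.98, roi, f).vessel.any()

    def test_monotone_shrinkage_with_threshold(self):
        rng = np.random.default_rng(5)
        u = rng.random(30)
        res, f, roi = self._setup(u)
        prev = defuzzify(res, 0, 0.0, roi, f).vessel
        for u0 in np.arange(0.02, 1.0, 0.02):
            cur = defuzzify(res, 0, float(u0), roi, f).vessel
            assert not np.any(cur & ~prev)  # subset of any lower threshold
            prev = cur

    def test_partition_of_roi(self):
        res, f, roi = self._setup([0.9, 0.6, 0.3])
        mask = defuzzify(res, 0, 0.5, roi, f)
        assert np.array_equal(mask.vessel | mask.parenchyma, roi)
        assert not np.any(mask.vessel & mask.parenchyma)

    def test_threshold_range_validated(self):
        res, f, roi = self._setup([0.9, 0.6, 0.3])
        with pytest.raises(InputError):
            defuzzify(res, 0, 1.0, roi, f)
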