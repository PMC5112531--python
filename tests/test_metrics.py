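"""Surface metrics against brute-force, analytic and reference oracles."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st
from scipy import stats

from gyrogen.metrics import (compute_mpc, compute_thickness, filter_r2,
                             fit_growth_rate, fit_growth_rates,
                             parcel_comparison, pooled_t_test,
                             split_by_mpc_sign)
from gyrogen.surfaces import TriSurface
from gyrogen.synthetic import table1_fixture


def grid_surface(n=8, spacing=1.0, z=0.0):
    xx, yy = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing)
    v = np.column_stack([xx.ravel(), yy.ravel(), np.full(n * n, float(z))])
    idx = np.arange(n * n).reshape(n, n)
    f = np.concatenate([
        np.stack([idx[:-1, :-1].ravel(), idx[:-1, 1:].ravel(), idx[1:, 1:].ravel()], 1),
        np.stack([idx[:-1, :-1].ravel(), idx[1:, 1:].ravel(), idx[1:, :-1].ravel()], 1)])
    return TriSurface(v, f)


class TestThickness:
    def test_parallel_planes_aligned_vertices(self):
        w = grid_surface(z=0.0)
        p = grid_surface(z=2.5)
        np.testing.assert_allclose(compute_thickness(w, p), 2.5)

    def test_identical_surfaces_zero(self):
        w = grid_surface()
        np.testing.assert_allclose(compute_thickness(w, w), 0.0)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_brute_force_all_pairs(self, seed):
        r = np.random.default_rng(seed)
        w = TriSurface(r.uniform(0, 10, (40, 3)), np.array([[0, 1, 2]]))
        p = TriSurface(r.uniform(0, 10, (60, 3)), np.array([[0, 1, 2]]))
        got = compute_thickness(w, p)
        brute = np.sqrt(((w.vertices[:, None] - p.vertices[None]) ** 2)
                        .sum(-1)).min(axis=1)
        np.testing.assert_allclose(got, brute, atol=1e-12)

    def test_empty_pial_rejected(self):
        w = grid_surface()
        with pytest.raises(ValueError):
            compute_thickness(w, TriSurface(np.empty((0, 3)),
                                            np.empty((0, 3), dtype=int)))


class TestMPC:
    def test_unit_sphere_positive_unit_curvature(self):
        s = trimesh.creation.icosphere(subdivisions=4)  # ~2.5k vertices
        surf = TriSurface(np.asarray(s.vertices), np.asarray(s.faces))
        mpc = compute_mpc(surf)
        assert np.isfinite(mpc).all()
        assert np.abs(mpc - 1.0).max() < 0.05

    def test_plane_is_flat(self):
        mpc = compute_mpc(grid_surface(n=10))
        interior = np.abs(mpc[np.isfinite(mpc)])
        assert interior.max() < 1e-8

    def test_cylinder_curvature_one_over_radius(self):
        radius = 2.0
        th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        zz = np.linspace(0, 10, 24)
        T, Z = np.meshgrid(th, zz, indexing="ij")
        v = np.column_stack([radius * np.cos(T).ravel(),
                             radius * np.sin(T).ravel(), Z.ravel()])
        idx = np.arange(64 * 24).reshape(64, 24)
        f = []
        for i in range(64):
            for j in range(23):
                i2 = (i + 1) % 64
                f += [[idx[i, j], idx[i2, j], idx[i2, j + 1]],
                      [idx[i, j], idx[i2, j + 1], idx[i, j + 1]]]
        surf = TriSurface(v, np.asarray(f))
        mpc = compute_mpc(surf)
        interior = np.abs(v[:, 2] - 5.0) < 3.0
        np.testing.assert_allclose(mpc[interior], 1.0 / radius, rtol=0.05)

    def test_sign_flips_with_orientation(self):
        s = trimesh.creation.icosphere(subdivisions=2)
        out = TriSurface(np.asarray(s.vertices), np.asarray(s.faces))
        inn = TriSurface(np.asarray(s.vertices), np.asarray(s.faces)[:, ::-1])
        np.testing.assert_allclose(compute_mpc(out), -compute_mpc(inn),
                                   atol=1e-9)


class TestRegression:
    WEEKS = np.arange(25, 32)

    def test_exact_line_recovered(self):
        y = 2.0 + 0.35 * (self.WEEKS - 25)
        res = fit_growth_rate(y, self.WEEKS)
        assert res.slope == pytest.approx(0.35, abs=1e-14)
        assert res.intercept == pytest.approx(2.0 - 0.35 * 25, abs=1e-10)
        assert res.r2 == pytest.approx(1.0, abs=1e-14)

    def test_constant_response_r2_zero(self):
        res = fit_growth_rate(np.full(7, 2.0), self.WEEKS)
        assert res.slope == 0.0
        assert res.r2 == 0.0

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_polyfit_oracle(self, seed):
        r = np.random.default_rng(seed)
        y = 2.0 + 0.2 * (self.WEEKS - 25) + r.normal(0, 0.3, 7)
        res = fit_growth_rate(y, self.WEEKS)
        slope, intercept = np.polyfit(self.WEEKS, y, 1)
        ss = stats.linregress(self.WEEKS, y)
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-8)
        assert res.r2 == pytest.approx(ss.rvalue**2, abs=1e-10)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(-50, 50))
    def test_slope_invariant_to_week_shift(self, shift):
        y = np.array([2.1, 2.2, 2.6, 2.7, 3.0, 3.2, 3.3])
        a = fit_growth_rate(y, self.WEEKS)
        b = fit_growth_rate(y, self.WEEKS + shift)
        assert a.slope == pytest.approx(b.slope, rel=1e-12)
        assert a.r2 == pytest.approx(b.r2, rel=1e-12)

    def test_vectorized_agrees_with_scalar(self, rng):
        y = rng.normal(2.5, 0.3, (7, 20)) + 0.2 * np.arange(7)[:, None]
        slopes, intercepts, r2 = fit_growth_rates(y, self.WEEKS)
        for j in (0, 7, 19):
            res = fit_growth_rate(y[:, j], self.WEEKS)
            assert slopes[j] == pytest.approx(res.slope, abs=1e-12)
            assert r2[j] == pytest.approx(res.r2, abs=1e-12)

    def test_too_few_timepoints_and_constant_weeks_rejected(self):
        with pytest.raises(ValueError):
            fit_growth_rate([1.0, 2.0], [25, 26])
        with pytest.raises(ValueError):
            fit_growth_rate([1.0, 2.0, 3.0], [25, 25, 25])


class TestFilterAndSplit:
    def test_filter_fractions(self):
        kept, frac = filter_r2(np.ones(10))
        assert frac == 1.0 and len(kept) == 10
        r2 = np.array([0.5] * 5 + [0.9] * 5)
        kept, frac = filter_r2(r2, threshold=0.6)
        assert frac == 0.5
        np.testing.assert_array_equal(kept, np.arange(5, 10))

    def test_threshold_inclusive_vs_strict(self):
        r2 = np.array([0.6])
        assert len(filter_r2(r2)[0]) == 1
        assert len(filter_r2(r2, strict=True)[0]) == 0

    def test_split_excludes_zero_and_nan(self):
        pos, neg = split_by_mpc_sign(np.array([-1.0, 1.0, 0.0, np.nan]))
        np.testing.assert_array_equal(pos, [1])
        np.testing.assert_array_equal(neg, [0])

    def test_sphere_is_single_group(self):
        s = trimesh.creation.icosphere(subdivisions=2)
        mpc = compute_mpc(TriSurface(np.asarray(s.vertices), np.asarray(s.faces)))
        pos, neg = split_by_mpc_sign(mpc)
        assert len(neg) == 0 and len(pos) == len(mpc)


class TestPooledT:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = pooled_t_test(a, a.copy())
        assert res.t == 0.0
        assert res.p_two_tail == pytest.approx(1.0)
        assert res.dof == 6

    def test_antisymmetry_under_swap(self):
        a = np.array([1.0, 2.0, 3.0])
        b = a + 1.0
        assert pooled_t_test(a, b).t == pytest.approx(-pooled_t_test(b, a).t)
        assert pooled_t_test(a, b).t < 0

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_scipy_reference(self, seed):
        r = np.random.default_rng(seed)
        a = r.normal(0.35, 0.26, 40)
        b = r.normal(0.10, 0.26, 55)
        res = pooled_t_test(a, b)
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
        t_r, p_r = stats.ttest_ind(a, b, equal_var=True, alternative="greater")
        assert res.t == pytest.approx(t_ref, abs=1e-10)
        assert res.p_two_tail == pytest.approx(p_ref, abs=1e-10)
        assert res.p_right_tail == pytest.approx(p_r, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pooled_t_test([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            pooled_t_test([1.0, 1.0], [2.0, 2.0])


class TestParcelComparison:
    def test_fixture_summary(self):
        res = parcel_comparison(table1_fixture())
        assert round(res.sulcal_mean, 2) == 2.59
        assert round(res.gyral_mean, 2) == 2.92
        assert res.test.t > 0
        assert res.test.p_right_tail < 1e-3

    def test_identical_classes_give_zero_t(self):
        import pandas as pd
        t = pd.DataFrame({"class": ["gyral"] * 3 + ["sulcal"] * 3,
                          "thickness_mm": [2.0, 2.5, 3.0] * 2})
        assert parcel_comparison(t).test.t == pytest.approx(0.0, abs=1e-12)

    def test_missing_class_rejected(self):
        import pandas as pd
        t = pd.DataFrame({"class": ["gyral"] * 3,
                          "thickness_mm": [2.0, 2.5, 3.0]})
        with pytest.raises(ValueError):
            parcel_comparison(t)
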