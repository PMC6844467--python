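"""Colour-mapping model: anchor points, projection, automatic thresholds and
the final per-voxel value, including its equivalence with the step-by-step
(project -> attenuate -> distance-cutoff) formulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import raccmap as rm
from raccmap.core import nearest_rank_percentile
from raccmap.regression import DemingFit, SampleStats

from conftest import stats_from_xy


def make_fit(beta0, beta1, lam=1.0):
    stats = SampleStats(n=3, mean_x=0.0, mean_y=beta0, s_xx=1.0, s_yy=beta1**2,
                        s_xy=beta1)
    return DemingFit(beta0=beta0, beta1=beta1, lam=lam, stats=stats)


def make_model(beta0=0.0, beta1=1.0, i_max=255.0, thr=(0.0, 0.0), theta=45.0,
               d_t=1.0, t_max=1.0):
    fit = make_fit(beta0, beta1)
    p0 = rm.intersect_p0(fit, rm.ColocThresholds(*thr))
    p1 = rm.intersect_p1(fit, i_max)
    p_max = p0 + t_max * (p1 - p0)
    return rm.RaccModel(fit=fit, p0=p0, p1=p1, p_max=p_max, t_max=t_max,
                        d_t=d_t, theta=theta, rescale=True, i_max=i_max)


def two_line_intersection(b0, b1, line):
    """Oracle: intersect y = b0 + b1*x with a vertical or horizontal line."""
    kind, v = line
    if kind == "x":
        return np.array([v, b0 + b1 * v])
    return np.array([(v - b0) / b1, v])


class TestAnchorPoints:
    @pytest.mark.parametrize("beta1,beta0,thr,expected_line", [
        (1.5, 0.0, (10, 20), ("y", 20)),  # threshold line y=20 is binding
        (1.0, 0.0, (0, 0), ("x", 0)),
        (2.0, 0.0, (50, 50), ("x", 50)),  # x=50 is binding (y there is 100)
    ])
    def test_p0_keeps_the_feasible_threshold_crossing(self, beta1, beta0, thr,
                                                      expected_line):
        fit = make_fit(beta0, beta1)
        p0 = rm.intersect_p0(fit, rm.ColocThresholds(*thr))
        expected = two_line_intersection(beta0, beta1, expected_line)
        np.testing.assert_allclose(p0, expected, atol=1e-12)
        # the crossing lies on the regression line and on the mask boundary
        assert p0[1] == pytest.approx(beta0 + beta1 * p0[0])
        assert p0[0] >= thr[0] and p0[1] >= thr[1]

    @pytest.mark.parametrize("beta1,beta0,expected", [
        (1.5, 0.0, (170.0, 255.0)),  # steep line hits the ceiling y = i_max
        (1.0, 0.0, (255.0, 255.0)),
        (0.5, 0.0, (255.0, 127.5)),  # shallow line exits at x = i_max
    ])
    def test_p1_meets_the_intensity_ceiling(self, beta1, beta0, expected):
        p1 = rm.intersect_p1(make_fit(beta0, beta1), 255.0)
        np.testing.assert_allclose(p1, expected, atol=1e-12)


class TestProjection:
    def test_point_on_the_line_projects_to_itself(self):
        p0, p1 = np.array([0.0, 0.0]), np.array([255.0, 255.0])
        p_i, t, d = rm.project(np.array([100.0, 100.0]), p0, p1)
        np.testing.assert_allclose(p_i, [100.0, 100.0])
        assert d == pytest.approx(0.0)

    def test_worked_perpendicular_geometry(self):
        p0, p1 = np.array([0.0, 0.0]), np.array([255.0, 255.0])
        p_i, t, d_raw = rm.project(np.array([100.0, 200.0]), p0, p1)
        np.testing.assert_allclose(p_i, [150.0, 150.0])
        assert d_raw == pytest.approx(np.sqrt(5000.0))
        assert d_raw / 255.0 == pytest.approx(0.27730, abs=5e-6)

    def test_q_at_p0_has_zero_parameter(self):
        p0, p1 = np.array([10.0, 20.0]), np.array([200.0, 250.0])
        _, t, _ = rm.project(p0.copy(), p0, p1)
        assert t == pytest.approx(0.0)

    def test_projection_matches_distance_minimizing_point(self):
        # oracle: densely sample the segment and find the closest point
        rng = np.random.default_rng(3)
        p0, p1 = np.array([20.0, 10.0]), np.array([240.0, 200.0])
        ts = np.linspace(-0.5, 1.5, 200001)
        line = p0 + ts[:, None] * (p1 - p0)
        for _ in range(5):
            q = rng.uniform(0, 255, size=2)
            p_i, t, d_raw = rm.project(q, p0, p1)
            k = np.argmin(np.linalg.norm(line - q, axis=1))
            assert t == pytest.approx(ts[k], abs=1e-5)
            assert d_raw == pytest.approx(np.linalg.norm(q - line[k]), abs=1e-4)


class TestAutomaticThresholds:
    def test_all_equal_distances_included_entirely(self):
        d = np.full(50, 0.123)
        assert rm.auto_distance_threshold(d) == 0.123

    def test_nearest_rank_on_uniform_grid(self):
        d = np.arange(100) / 100.0  # 0.00 .. 0.99
        d_t = rm.auto_distance_threshold(d)
        assert d_t == pytest.approx(0.98)  # rank ceil(0.99*100) = 99
        assert (d <= d_t).mean() >= 0.99

    def test_included_fraction_on_heavy_tailed_sample(self):
        rng = np.random.default_rng(0)
        d = np.abs(rng.normal(0, 0.1, size=10_000))
        d_t = rm.auto_distance_threshold(d)
        assert (d <= d_t).mean() >= 0.99

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError):
            nearest_rank_percentile(np.array([]))

    def test_pmax_saturates_at_p1(self):
        p0, p1 = np.array([0.0, 0.0]), np.array([255.0, 255.0])
        p_max, t_max = rm.auto_pmax(np.full(10, 1.0), p0, p1)
        np.testing.assert_allclose(p_max, p1)
        assert t_max == 1.0
        # projections beyond p1 are clamped back to the ceiling
        p_max, t_max = rm.auto_pmax(np.full(10, 1.4), p0, p1)
        assert t_max == 1.0

    def test_pmax_nearest_rank_on_uniform_grid(self):
        t = np.arange(1, 101) / 100.0  # 0.01 .. 1.00
        p0, p1 = np.array([0.0, 0.0]), np.array([200.0, 100.0])
        p_max, t_max = rm.auto_pmax(t, p0, p1)
        assert t_max == pytest.approx(0.99)
        np.testing.assert_allclose(p_max, p0 + 0.99 * (p1 - p0))

    def test_rescale_off_retains_p1(self):
        p0, p1 = np.array([0.0, 0.0]), np.array([200.0, 100.0])
        p_max, t_max = rm.auto_pmax(np.full(5, 0.2), p0, p1, rescale=False)
        np.testing.assert_allclose(p_max, p1)
        assert t_max == 1.0


def sequential_value(q, model):
    """Independent oracle: the step-by-step formulation — linear position
    along p0 -> p_max clamped to [0, 1], then linear attenuation by
    d*tan(theta), then the distance cutoff."""
    _, t, d_raw = rm.project(q, model.p0, model.p1)
    d = d_raw / model.i_max
    u = t / model.t_max  # position along p0 -> p_max
    c = np.clip(u, 0.0, 1.0)
    pen = d * np.tan(np.deg2rad(model.theta))
    c = np.where(c > pen, c - pen, 0.0)
    return np.where(d <= model.d_t, c, 0.0)


class TestColourmapValue:
    def test_at_pmax_on_line_scores_one(self):
        model = make_model(t_max=0.8)
        q = model.p_max
        assert rm.colourmap_value(q, model) == pytest.approx(1.0)

    def test_at_p0_scores_zero(self):
        model = make_model()
        assert rm.colourmap_value(model.p0, model) == pytest.approx(0.0)

    def test_worked_example_on_the_diagonal(self):
        # line y=x, thresholds 0, no rescale, theta=45: q=(100,200)
        model = make_model(theta=45.0)
        c = rm.colourmap_value(np.array([100.0, 200.0]), model)
        expected = 10.0 / 17.0 - np.sqrt(5000.0) / 255.0
        assert c == pytest.approx(expected, abs=1e-12)
        assert c == pytest.approx(0.31094, abs=5e-6)

    def test_theta_zero_disables_attenuation(self):
        model = make_model(theta=0.0)
        c = rm.colourmap_value(np.array([100.0, 200.0]), model)
        assert c == pytest.approx(10.0 / 17.0, abs=1e-12)

    def test_distance_cutoff_zeroes_the_value(self):
        model = make_model(theta=45.0, d_t=0.2)
        assert rm.colourmap_value(np.array([100.0, 200.0]), model) == 0.0

    def test_beyond_pmax_saturates_minus_penalty(self):
        model = make_model(theta=45.0, t_max=0.5)
        q = np.array([200.0, 210.0])  # projects beyond p_max
        _, t, d_raw = rm.project(q, model.p0, model.p1)
        assert t / model.t_max >= 1.0
        expected = 1.0 - (d_raw / 255.0) * np.tan(np.deg2rad(45.0))
        assert rm.colourmap_value(q, model) == pytest.approx(expected)

    def test_negative_projection_clamps_to_zero(self):
        model = make_model(beta0=50.0, thr=(20.0, 20.0))
        q = np.array([0.0, 0.0])
        assert rm.colourmap_value(q, model) == 0.0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        x=st.floats(0, 255), y=st.floats(0, 255),
        theta=st.floats(0, 89.0),
        beta1=st.floats(0.2, 5.0),
    )
    def test_value_always_in_unit_interval(self, x, y, theta, beta1):
        model = make_model(beta1=beta1, theta=theta)
        c = rm.colourmap_value(np.array([x, y]), model)
        assert 0.0 <= c <= 1.0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(x=st.floats(1, 255), y=st.floats(1, 255),
           t1=st.floats(0, 89.0), t2=st.floats(0, 89.0))
    def test_monotone_nonincreasing_in_theta(self, x, y, t1, t2):
        lo, hi = sorted((t1, t2))
        q = np.array([x, y])
        c_lo = rm.colourmap_value(q, make_model(theta=lo))
        c_hi = rm.colourmap_value(q, make_model(theta=hi))
        assert c_hi <= c_lo + 1e-12

    def test_monotone_along_the_line(self):
        model = make_model(theta=60.0)
        ts = np.linspace(0, 1, 25)
        pts = model.p0 + ts[:, None] * (model.p1 - model.p0)
        cs = rm.colourmap_value(pts, model)
        assert np.all(np.diff(cs) >= -1e-12)

    def test_near_ninety_degrees_suppresses_off_line_voxels(self):
        model = make_model(theta=89.9)
        rng = np.random.default_rng(1)
        q = rng.uniform(0, 255, size=(500, 2))
        _, _, d_raw = rm.project(q, model.p0, model.p1)
        off = d_raw / 255.0 > 0.01
        c = rm.colourmap_value(q, model)
        assert np.all(c[off] < 1e-3)

    @pytest.mark.parametrize("theta", [0.0, 30.0, 45.0, 75.0])
    def test_equivalence_with_sequential_formulation(self, theta):
        rng = np.random.default_rng(42)
        q = rng.uniform(0, 255, size=(2000, 2))
        model = make_model(beta0=5.0, beta1=1.3, thr=(10.0, 15.0),
                           theta=theta, d_t=0.25, t_max=0.8)
        got = rm.colourmap_value(q, model)
        want = sequential_value(q, model)
        np.testing.assert_allclose(got, want, atol=1e-12)


class TestScoreVolume:
    def test_invalid_theta_rejected(self, cylinders_pair):
        for theta in (-1.0, 90.0, 120.0):
            with pytest.raises(ValueError):
                rm.score_volume(cylinders_pair, rm.ColocThresholds(0, 0), theta=theta)

    def test_scores_zero_outside_mask_and_in_unit_interval(self, noisy_spheres_run):
        pair, thr, score, model = noisy_spheres_run
        mask = rm.coloc_mask(pair, thr)
        assert np.all(score.c[~mask] == 0.0)
        assert np.all(score.c[~score.coloc] == 0.0)
        assert np.all((score.c >= 0.0) & (score.c <= 1.0))

    def test_coverage_of_automatic_thresholds(self, noisy_spheres_run):
        pair, thr, score, model = noisy_spheres_run
        d = score.distances[~np.isnan(score.distances)]
        assert (d <= model.d_t).mean() >= 0.99
        mask = rm.coloc_mask(pair, thr)
        q = np.stack([pair.ch1[mask], pair.ch2[mask]], axis=-1).astype(float)
        _, t, _ = rm.project(q, model.p0, model.p1)
        assert (t <= model.t_max).mean() >= 0.99
        assert score.coloc.sum() <= mask.sum()
        assert score.coloc.sum() >= 0.99 * mask.sum()

    def test_identical_cylinders_scores_do_not_depend_on_theta(self, cylinders_pair):
        thr = rm.ColocThresholds(0, 0)
        s0, _ = rm.score_volume(cylinders_pair, thr, theta=0.0)
        s89, m = rm.score_volume(cylinders_pair, thr, theta=89.0)
        np.testing.assert_array_equal(s0.c, s89.c)
        assert np.nanmax(s89.distances) == 0.0

    def test_identical_cylinders_scores_decrease_radially(self, cylinders_pair):
        thr = rm.ColocThresholds(0, 0)
        # rescale off: the saturation point would clip the innermost shell
        score, _ = rm.score_volume(cylinders_pair, thr, theta=45.0, rescale=False)
        # walk outward from the cylinder axis, perpendicular to it
        profile = score.c[32, 32:42, 32]
        assert profile[0] > 0
        positive = profile[profile > 0]
        assert np.all(np.diff(positive) < 0)

    def test_roi_restriction_refits_on_the_bounding_box(self, noisy_spheres_pair,
                                                        noisy_thresholds):
        roi = (slice(16, 48), slice(16, 48), slice(16, 48))
        score, model = rm.score_volume(noisy_spheres_pair, noisy_thresholds, roi=roi)
        assert score.c.shape == (32, 32, 32)
        full_score, full_model = rm.score_volume(noisy_spheres_pair, noisy_thresholds)
        assert model.fit.stats.n <= full_model.fit.stats.n
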