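"""Polygon morphometrics, AZ distance profiles, and distribution comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from matplotlib.path import Path as MplPath
from scipy import stats

from ctsyn import synth, ultrastructure as us
from ctsyn.ultrastructure import (
    TerminalAnnotation,
    az_distance_profile,
    compare_profiles,
    max_feret,
    point_density,
    polygon_area,
    polyline_length,
    read_annotation,
    terminal_metrics,
    write_annotation,
)


def _random_polygon(rng, n=12, radius=300.0):
    ang = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = radius * rng.uniform(0.6, 1.4, n)
    return np.column_stack([r * np.cos(ang), r * np.sin(ang)])


class TestPolygonArea:
    def test_square_and_triangle(self):
        square = np.array([[0, 0], [100, 0], [100, 100], [0, 100]], dtype=float)
        assert polygon_area(square) == pytest.approx(0.01)  # 1e4 nm^2
        tri = np.array([[0, 0], [200, 0], [0, 200]], dtype=float)
        assert polygon_area(tri) == pytest.approx(0.02)

    def test_orientation_independent(self):
        square = np.array([[0, 0], [100, 0], [100, 100], [0, 100]], dtype=float)
        assert polygon_area(square[::-1]) == polygon_area(square)

    def test_monte_carlo_oracle(self, rng):
        poly = _random_polygon(rng)
        # independent MC oracle via matplotlib's point-in-polygon
        lo, hi = poly.min(0), poly.max(0)
        pts = rng.uniform(lo, hi, (200000, 2))
        frac = MplPath(poly).contains_points(pts).mean()
        mc_area_um2 = frac * np.prod(hi - lo) / 1e6
        assert polygon_area(poly) == pytest.approx(mc_area_um2, rel=0.01)

    def test_self_intersecting_rejected(self):
        bowtie = np.array([[0, 0], [100, 100], [100, 0], [0, 100]], dtype=float)
        with pytest.raises(ValueError):
            polygon_area(bowtie)


class TestMaxFeret:
    def test_square_diagonal(self):
        square = np.array([[0, 0], [100, 0], [100, 100], [0, 100]], dtype=float)
        assert max_feret(square) == pytest.approx(100 * np.sqrt(2))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_equals_all_pairs_brute_force(self, seed):
        poly = _random_polygon(np.random.default_rng(seed))
        d = poly[:, None, :] - poly[None, :, :]
        brute = np.sqrt((d ** 2).sum(-1)).max()
        assert max_feret(poly) == pytest.approx(brute, rel=1e-12)


class TestPointDensity:
    def test_trivial_counts(self):
        square_um = np.array([[0, 0], [1000, 0], [1000, 1000], [0, 1000]], dtype=float)
        assert point_density(np.empty((0, 2)), square_um) == 0.0
        pts = np.random.default_rng(0).uniform(0, 1000, (50, 2))
        assert point_density(pts, square_um) == pytest.approx(50.0)

    def test_boundary_points_count_as_inside(self):
        square = np.array([[0, 0], [1000, 0], [1000, 1000], [0, 1000]], dtype=float)
        assert point_density(np.array([[0.0, 500.0]]), square) == pytest.approx(1.0)

    def test_density_times_area_conserves_count(self, rng):
        poly = _random_polygon(rng)
        pts = rng.uniform(poly.min(0), poly.max(0), (200, 2))
        inside = MplPath(poly).contains_points(pts).sum()
        est = point_density(pts, poly) * polygon_area(poly)
        assert round(est) == pytest.approx(inside, abs=2)  # edge convention slack


class TestAZDistanceProfile:
    def test_point_above_midpoint(self):
        az = np.array([[0.0, 0.0], [200.0, 0.0]])
        prof = az_distance_profile(np.array([[100.0, 50.0]]), az)
        row = prof.iloc[0]
        assert row["distance_nm"] == pytest.approx(50.0)
        assert row["normalized"] == pytest.approx(0.25)
        assert row["included"]

    def test_point_beyond_endpoint_excluded(self):
        az = np.array([[0.0, 0.0], [200.0, 0.0]])
        prof = az_distance_profile(np.array([[300.0, 50.0]]), az)
        assert not prof.iloc[0]["included"]

    def test_matches_dense_sampling_oracle(self, rng):
        # jagged 4-segment polyline
        az = np.array([[0, 0], [120, 40], [260, 10], [380, 70]], dtype=float)
        pts = rng.uniform([0, -150], [380, 200], (60, 2))
        prof = az_distance_profile(pts, az)
        # dense oracle: 0.02-nm sampling of the polyline
        samples = []
        for a, b in zip(az[:-1], az[1:]):
            n = int(np.linalg.norm(b - a) / 0.02)
            t = np.linspace(0, 1, n)[:, None]
            samples.append(a + t * (b - a))
        samples = np.vstack(samples)
        for p, (_, row) in zip(pts, prof.iterrows()):
            if row["included"]:
                oracle = np.sqrt(((samples - p) ** 2).sum(1)).min()
                assert row["distance_nm"] == pytest.approx(oracle, abs=0.5)

    def test_rigid_motion_invariance(self, rng):
        az = np.array([[0, 0], [120, 40], [260, 10]], dtype=float)
        pts = rng.uniform([0, -100], [260, 150], (40, 2))
        base = az_distance_profile(pts, az)
        theta = 0.83
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([512.3, -77.7])
        moved = az_distance_profile(pts @ R.T + shift, az @ R.T + shift)
        np.testing.assert_allclose(
            base["distance_nm"], moved["distance_nm"], atol=1e-9, equal_nan=True
        )
        np.testing.assert_array_equal(base["included"], moved["included"])

    def test_zero_length_active_zone_rejected(self):
        with pytest.raises(ValueError):
            az_distance_profile(np.array([[0.0, 1.0]]), np.array([[0.0, 0.0], [0.0, 0.0]]))


class TestCompareProfiles:
    def test_identical_samples_have_zero_distance(self, rng):
        x = rng.normal(0, 1, 300)
        d, p = compare_profiles(x, x.copy())
        assert d == 0.0

    def test_shifted_distributions_detected(self, rng):
        a = rng.normal(0.0, 1.0, 150)
        b = rng.normal(1.0, 1.0, 150)
        d, p = compare_profiles(a, b)
        assert p < 0.001

    def test_null_calibration(self):
        # p-values approximately uniform under the null
        hits = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            _, p = compare_profiles(r.normal(0, 1, 500), r.normal(0, 1, 500))
            hits += p < 0.05
        se = np.sqrt(0.05 * 0.95 / 200)
        assert abs(hits / 200 - 0.05) < 3 * se + 1e-9

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_profiles(np.empty(0), np.ones(5))


class TestGenotypeContrast:
    def test_gold_reduction_detected_vesicles_unchanged(self):
        wt = synth.simulate_terminals(123, gold_density=40.0, seed=21)
        hemi = synth.simulate_terminals(181, gold_density=40.0 * (1 - 0.289), seed=22)

        def densities(terms, kind):
            return np.array([point_density(t.points_of(kind), t.membrane) for t in terms])

        gw, gh = densities(wt, "gold"), densities(hemi, "gold")
        vw, vh = densities(wt, "vesicle"), densities(hemi, "vesicle")
        assert compare_profiles(gw, gh)[1] < 0.05
        assert stats.mannwhitneyu(gw, gh).pvalue < 0.05
        assert compare_profiles(vw, vh)[1] > 0.05
        assert stats.mannwhitneyu(vw, vh).pvalue > 0.05
        reduction = 1.0 - np.median(gh) / np.median(gw)
        assert reduction == pytest.approx(0.289, abs=0.06)


class TestAnnotationIO:
    def test_json_round_trip_and_metrics(self, tmp_path):
        ann = synth.simulate_terminals(1, seed=5)[0]
        path = tmp_path / "terminal.json"
        write_annotation(ann, path)
        back = read_annotation(path)
        np.testing.assert_allclose(back.membrane, ann.membrane)
        np.testing.assert_allclose(back.points, ann.points)
        assert list(back.kinds) == list(ann.kinds)
        m = terminal_metrics(back)
        assert m.area_um2 > 0
        assert m.az_length_nm == pytest.approx(polyline_length(ann.active_zone))
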