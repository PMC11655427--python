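"""Full-harmonic phasor transform, triangle geometry, barycentric unmixing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from npqunmix import (
    barycentric_abundances,
    pc_vertex,
    phasor_transform,
    third_vertex,
)
from npqunmix.errors import (
    DegenerateTriangleError,
    ExcessiveClippingError,
    UndefinedPhasorError,
    ValidationError,
)
from npqunmix.phasor import PhasorPoint, TriangleModel, inflate_triangle, raw_barycentric
from npqunmix.synth import canonical_profiles

GRID = np.arange(10.0, 601.0, 10.0)


def brute_force_phasor(y, h):
    """Direct double-loop DFT oracle."""
    n = len(y)
    gs, ss = [], []
    f0 = sum(y)
    for k in range(1, h + 1):
        re = sum(y[j] * np.cos(2 * np.pi * k * j / n) for j in range(n))
        im = -sum(y[j] * np.sin(2 * np.pi * k * j / n) for j in range(n))
        gs.append(re / f0)
        ss.append(-im / f0)
    return np.mean(gs), np.mean(ss)


class TestPhasorTransform:
    def test_constant_curve_maps_to_origin(self):
        p = phasor_transform(np.full(16, 2.0))
        assert (p.g, p.s) == (pytest.approx(0.0, abs=1e-15),
                              pytest.approx(0.0, abs=1e-15))

    def test_single_harmonic_closed_form(self):
        j = np.arange(8)
        p = phasor_transform(1 + np.cos(2 * np.pi * j / 8), n_harmonics=3)
        assert p.g == pytest.approx(1 / 6, abs=1e-12)
        assert p.s == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_dft_oracle(self, rng):
        for _ in range(10):
            y = rng.uniform(0, 2, 24)
            h = int(rng.integers(1, 11))
            p = phasor_transform(y, n_harmonics=h)
            g, s = brute_force_phasor(list(y), h)
            assert p.g == pytest.approx(g, abs=1e-12)
            assert p.s == pytest.approx(s, abs=1e-12)

    def test_zero_sum_curve_undefined(self):
        with pytest.raises(UndefinedPhasorError):
            phasor_transform(np.zeros(10))

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError):
            phasor_transform(np.ones(3))

    @given(seed=st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_mixture_phasor_is_area_weighted_barycentre(self, seed):
        """Phasor linearity: the property that makes barycentric unmixing
        exact for any harmonic count."""
        rng = np.random.default_rng(seed)
        shapes = canonical_profiles(GRID, "wt")
        P = np.vstack([s.values(GRID) for s in shapes])
        a = rng.uniform(0.05, 2.0, 3)
        h = int(rng.integers(1, 30))
        mix = phasor_transform(a @ P, n_harmonics=h)
        areas = P.sum(axis=1)
        w = a * areas / (a * areas).sum()
        pure = np.array([phasor_transform(p, n_harmonics=h).as_array() for p in P])
        expected = w @ pure
        assert mix.g == pytest.approx(expected[0], abs=1e-12)
        assert mix.s == pytest.approx(expected[1], abs=1e-12)


class TestPcVertex:
    def _pca_like(self):
        shapes = canonical_profiles(GRID, "wt")
        mean = shapes[0].values(GRID) + 0.5 * shapes[1].values(GRID)
        comp = shapes[1].values(GRID) - shapes[1].values(GRID).mean()
        comp /= np.linalg.norm(comp)
        return mean, comp

    def test_zero_scale_recovers_mean_phasor(self):
        mean, comp = self._pca_like()
        v = pc_vertex(mean, comp, 0.0, n_harmonics=10)
        c = phasor_transform(mean, n_harmonics=10)
        assert (v.g, v.s) == (pytest.approx(c.g), pytest.approx(c.s))

    def test_scale_moves_vertex_monotonically_toward_pure_phasor(self):
        mean, comp = self._pca_like()
        target = phasor_transform(
            canonical_profiles(GRID, "wt")[1].values(GRID), n_harmonics=10
        ).as_array()
        dists = []
        for scale in (0.0, 1.5, 3.0):
            v = pc_vertex(mean, comp, scale, n_harmonics=10).as_array()
            dists.append(np.linalg.norm(v - target))
        assert dists[0] > dists[1] > dists[2]

    def test_excessive_clipping_rejected(self):
        mean, comp = self._pca_like()
        with pytest.raises(ExcessiveClippingError):
            pc_vertex(mean, comp, -1e4, n_harmonics=10)


class TestThirdVertex:
    def test_unit_triangle(self):
        v = third_vertex(PhasorPoint(0, 0), PhasorPoint(1, 0),
                         PhasorPoint(1 / 3, 1 / 3))
        assert (v.g, v.s) == (pytest.approx(0.0), pytest.approx(1.0))

    def test_roundtrip_over_random_triangles(self, rng):
        for _ in range(1000):
            verts = rng.normal(0, 1, (3, 2))
            c = PhasorPoint(*verts.mean(axis=0))
            v3 = third_vertex(PhasorPoint(*verts[0]), PhasorPoint(*verts[1]), c)
            np.testing.assert_allclose([v3.g, v3.s], verts[2], atol=1e-12)

    def test_centroid_identity(self):
        v1, v2 = PhasorPoint(0.3, -1.2), PhasorPoint(2.0, 0.7)
        c = PhasorPoint(0.11, 0.013)
        v3 = third_vertex(v1, v2, c)
        centroid = (np.array([v1.g, v1.s]) + [v2.g, v2.s] + [v3.g, v3.s]) / 3
        np.testing.assert_allclose(centroid, [c.g, c.s], atol=1e-15)


class TestBarycentric:
    TRI = TriangleModel(PhasorPoint(0, 0), PhasorPoint(1, 0), PhasorPoint(0, 1),
                        centroid=PhasorPoint(1 / 3, 1 / 3))

    def test_vertex_is_pure(self):
        w, clipped = barycentric_abundances(PhasorPoint(0, 0), self.TRI)
        np.testing.assert_allclose(w, [1, 0, 0], atol=1e-12)
        assert not clipped

    def test_centroid_is_uniform(self):
        w, _ = barycentric_abundances(PhasorPoint(1 / 3, 1 / 3), self.TRI)
        np.testing.assert_allclose(w, [1 / 3, 1 / 3, 1 / 3], atol=1e-12)

    def test_outside_point_is_clipped_and_renormalised(self):
        w, clipped = barycentric_abundances(PhasorPoint(-0.2, 0.5), self.TRI)
        assert clipped
        assert w.sum() == pytest.approx(1.0)
        assert np.all(w >= 0)

    def test_collinear_triangle_rejected(self):
        with pytest.raises(DegenerateTriangleError):
            TriangleModel(PhasorPoint(0, 0), PhasorPoint(1, 1),
                          PhasorPoint(2, 2), centroid=PhasorPoint(1, 1))

    def test_mixture_abundances_equal_area_weighted_fractions(self, rng):
        """Noiseless mixtures unmix to exact intensity-weighted fractions
        when the triangle vertices sit at the pure-component phasors."""
        shapes = canonical_profiles(GRID, "wt")
        P = np.vstack([s.values(GRID) for s in shapes])
        pure = [phasor_transform(p, n_harmonics=10) for p in P]
        tri = TriangleModel(*pure, centroid=PhasorPoint(
            *(np.mean([[p.g, p.s] for p in pure], axis=0))))
        areas = P.sum(axis=1)
        for _ in range(20):
            a = rng.uniform(0.05, 2.0, 3)
            w_true = a * areas / (a * areas).sum()
            p = phasor_transform(a @ P, n_harmonics=10)
            w, _ = barycentric_abundances(p, tri)
            np.testing.assert_allclose(w, w_true, atol=1e-10)

    def test_abundances_invariant_to_global_rescaling(self):
        shapes = canonical_profiles(GRID, "wt")
        P = np.vstack([s.values(GRID) for s in shapes])
        pure = [phasor_transform(p, n_harmonics=10) for p in P]
        tri = TriangleModel(*pure, centroid=PhasorPoint(
            *(np.mean([[p.g, p.s] for p in pure], axis=0))))
        y = np.array([0.5, 1.2, 0.3]) @ P
        w1, _ = barycentric_abundances(phasor_transform(y, 10), tri)
        w2, _ = barycentric_abundances(phasor_transform(7.0 * y, 10), tri)
        np.testing.assert_allclose(w1, w2, atol=1e-12)


def test_inflation_rescales_barycentric_coordinates(rng):
    tri = TriangleModel(PhasorPoint(0, 0), PhasorPoint(1, 0), PhasorPoint(0, 1),
                        centroid=PhasorPoint(1 / 3, 1 / 3))
    pts = rng.uniform(-0.3, 1.0, (50, 2))
    inflated, f = inflate_triangle(pts, tri, quantile=1.0)
    w = raw_barycentric(pts, inflated)
    assert f >= 1.0
    assert np.all(w >= -1e-9)
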