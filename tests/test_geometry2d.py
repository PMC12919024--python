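import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cellshapes as cs
from cellshapes.geometry2d import (_design_matrix, evaluate_fourier,
                                   read_boundaries_csv, shapes_to_frame,
                                   frame_to_shapes, write_boundaries_csv)


def ellipse(a, b, center=(0.0, 0.0), angle=0.0, n=512):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x, y = a * np.cos(th), b * np.sin(th)
    ca, sa = np.cos(angle), np.sin(angle)
    return cs.Boundary2D(np.column_stack(
        [center[0] + ca * x - sa * y, center[1] + sa * x + ca * y]))


class TestAlign:
    def test_centered_at_origin(self):
        b = cs.align_boundary(ellipse(3, 1, center=(5, 5)))
        assert np.abs(b.centroid()).max() < 1e-9

    def test_rotated_ellipse_major_axis_on_x(self):
        b = cs.align_boundary(ellipse(3, 1, angle=np.deg2rad(30)))
        # extent along x must dominate and match the major diameter
        ext = b.points.max(axis=0) - b.points.min(axis=0)
        assert ext[0] == pytest.approx(6.0, rel=1e-3)
        assert ext[1] == pytest.approx(2.0, rel=1e-3)

    def test_idempotent_on_asymmetric_shape(self):
        th = np.linspace(0, 2 * np.pi, 600, endpoint=False)
        r = 10 + 3 * np.cos(th) + 1.5 * np.sin(2 * th) + np.cos(3 * th)
        b = cs.Boundary2D(np.column_stack([r * np.cos(th), r * np.sin(th)]))
        once = cs.align_boundary(b)
        twice = cs.align_boundary(once)
        assert np.abs(once.points - twice.points).max() < 1e-9

    def test_translation_equivariance(self):
        th = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        r = 8 + 2 * np.cos(3 * th) + np.sin(th)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
        f1, _ = cs.fit_boundary(cs.Boundary2D(pts), 8)
        f2, _ = cs.fit_boundary(cs.Boundary2D(pts + [17.0, -4.0]), 8)
        assert np.abs(f1.flatten() - f2.flatten()).max() < 1e-9

    def test_isotropic_scatter_warns_and_keeps_orientation(self, circle_boundary):
        with pytest.warns(UserWarning, match="isotropic"):
            cs.align_boundary(circle_boundary)

    def test_zero_area_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 10), np.zeros(10)])
        with pytest.raises(ValueError):
            cs.Boundary2D(pts)


class TestArclength:
    def test_unit_circle_is_cos_sin(self, circle_boundary):
        theta, xy = cs.arclength_parameterize(circle_boundary, 360)
        assert np.abs(xy[:, 0] - np.cos(theta)).max() < 1e-5
        assert np.abs(xy[:, 1] - np.sin(theta)).max() < 1e-5

    def test_square_halfway_point_is_diametrically_opposite(self):
        # square of side 2, corners at (+-1, +-1); start = (1, 1) (max x, max y)
        pts = []
        for a, b in [((1, 1), (-1, 1)), ((-1, 1), (-1, -1)),
                     ((-1, -1), (1, -1)), ((1, -1), (1, 1))]:
            seg = np.linspace(a, b, 50, endpoint=False)
            pts.append(seg)
        sq = cs.Boundary2D(np.vstack(pts))
        theta, xy = cs.arclength_parameterize(sq, 8)
        k = np.argmin(np.abs(theta - np.pi))
        # half the perimeter (4 of 8) along the square from (1,1) is (-1,-1)
        assert xy[k] == pytest.approx([-1.0, -1.0], abs=1e-6)

    def test_uniform_theta_spacing(self, star_boundary):
        theta, _ = cs.arclength_parameterize(star_boundary, 360)
        gaps = np.diff(np.append(theta, 2 * np.pi))
        assert np.abs(gaps - 2 * np.pi / 360).max() < 1e-12


class TestFourierFit:
    def test_unit_circle_first_harmonic_only(self, circle_boundary):
        theta, xy = cs.arclength_parameterize(circle_boundary, 360)
        f, diag = cs.fit_fourier(theta, xy, 1)
        assert f.a[0] == pytest.approx(1.0, abs=1e-6)
        assert f.d[0] == pytest.approx(1.0, abs=1e-6)
        for val in (f.a0, f.c0, f.b[0], f.c[0]):
            assert abs(val) < 1e-6

    def test_feature_counts(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=15)
        body = cs.FourierShape(15, 1.0, 1.0, z, z, z, z)
        nucleus = cs.FourierShape(5, 1.0, 1.0, z[:5], z[:5], z[:5], z[:5])
        assert body.n_features == 62
        assert nucleus.n_features == 22
        concat = np.concatenate([body.flatten(), nucleus.flatten()])
        assert len(concat) == 84

    def test_matches_normal_equations_oracle(self, star_boundary):
        theta, xy = cs.arclength_parameterize(star_boundary, 180)
        f, _ = cs.fit_fourier(theta, xy, 8)
        A = _design_matrix(theta, 8)
        oracle = np.linalg.solve(A.T @ A, A.T @ xy)
        fitted = np.column_stack([
            np.concatenate([[f.a0], f.a, f.b]),
            np.concatenate([[f.c0], f.c, f.d]),
        ])
        assert np.abs(fitted - oracle).max() / np.abs(oracle).max() < 1e-8

    def test_underdetermined_refused(self, star_boundary):
        theta, xy = cs.arclength_parameterize(star_boundary, 10)
        with pytest.raises(ValueError, match="underdetermined"):
            cs.fit_fourier(theta, xy, 10)

    def test_flatten_round_trip(self):
        rng = np.random.default_rng(3)
        f = cs.FourierShape(7, 2.0, -1.0, *rng.normal(size=(4, 7)))
        g = cs.FourierShape.from_flat(f.flatten())
        assert np.array_equal(f.flatten(), g.flatten())


class TestReconstruct:
    def test_constant_term_degenerates_to_point(self):
        f = cs.FourierShape(1, 2.0, 0.0, [0.0], [0.0], [0.0], [0.0])
        pts = evaluate_fourier(f, np.linspace(0, 2 * np.pi, 16))
        assert np.abs(pts - [1.0, 0.0]).max() < 1e-12  # a0/2 convention

    def test_circle_round_trip_radial_error(self, circle_boundary):
        f, _ = cs.fit_boundary(circle_boundary, 3, align=False)
        rec = cs.reconstruct_fourier(f, 512)
        radii = np.hypot(rec.points[:, 0], rec.points[:, 1])
        assert np.abs(radii - 1.0).max() < 1e-6

    def test_fit_reconstruct_fit_fixed_point(self, star_boundary):
        # refitting the reconstruction sampled in the same theta basis is a
        # projection onto a space that already contains it: exact fixed point
        f1, _ = cs.fit_boundary(star_boundary, 8, align=False)
        theta = 2 * np.pi * np.arange(720) / 720
        f2, _ = cs.fit_fourier(theta, evaluate_fourier(f1, theta), 8)
        assert np.abs(f1.flatten() - f2.flatten()).max() < 1e-8

    def test_higher_order_fit_not_worse(self, star_boundary):
        _, d5 = cs.fit_boundary(star_boundary, 5, align=False)
        _, d15 = cs.fit_boundary(star_boundary, 15, align=False)
        assert d15.rss <= d5.rss + 1e-12


class TestSelectHarmonics:
    def test_circle_rss_tiny_for_all_orders(self, circle_boundary):
        tab = cs.select_harmonics(circle_boundary, 5)
        assert (tab["rss"] < 1e-10).all()

    def test_five_lobed_star_elbow_at_lobe_frequency(self, star_boundary):
        # a radial 5-lobe modulation r = R + A cos(5t) enters the Cartesian
        # contour as cos(5t)cos(t) etc., i.e. at harmonics 4 and 6: the RSS
        # table is flat through n=3 and collapses once both sidebands fit
        tab = cs.select_harmonics(star_boundary, 8).set_index("n")["rss"]
        assert tab[3] == pytest.approx(tab[1], rel=1e-9)  # no lobe content below 4
        assert tab[4] < 0.5 * tab[3]
        assert tab[6] < 0.02 * tab[3]  # elbow complete at the upper sideband

    def test_rss_monotone_non_increasing(self, star_boundary):
        rss = cs.select_harmonics(star_boundary, 10)["rss"].to_numpy()
        assert (np.diff(rss) <= 1e-12).all()


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 10_000))
def test_random_star_shapes_have_monotone_rss(seed):
    """Nested least squares: RSS never increases with harmonic order."""
    rng = np.random.default_rng(seed)
    b = cs.fixtures.make_boundary(rng, elongation=rng.uniform(1, 3),
                                  n_protrusions=int(rng.integers(0, 6)),
                                  protrusion_amplitude=2.0, noise_sd=0.3)
    rss = cs.select_harmonics(b, 8, n_samples=120)["rss"].to_numpy()
    assert (np.diff(rss) <= 1e-12).all()


def test_boundary_csv_round_trip(tmp_path, star_boundary):
    path = tmp_path / "b.csv"
    write_boundaries_csv(path, {"c1": star_boundary})
    back = read_boundaries_csv(path)
    assert np.abs(back["c1"].points - star_boundary.points).max() < 1e-12


def test_shape_frame_round_trip(star_boundary):
    # align=False: the 5-fold symmetric star has an isotropic point scatter,
    # so alignment would (correctly) warn about the undefined principal axis
    f, _ = cs.fit_boundary(star_boundary, 6, align=False)
    df = shapes_to_frame({"c1": {"body": f}})
    back = frame_to_shapes(df)["c1"]["body"]
    assert np.array_equal(back.flatten(), f.flatten())
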