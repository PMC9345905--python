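"""Grasp matrix, friction pyramids, soft-contact pairs, and the facet stack."""

import numpy as np
import pytest

from precigrip import (
    Contact,
    assemble_facet_matrix,
    friction_pyramid,
    grasp_matrix,
    sensing_device,
    soft_contact_pair,
)
from precigrip.mechanics import skew


def _contact(point, normal=(0, 0, 1)):
    return Contact(point=np.asarray(point, float), normal=np.asarray(normal, float),
                   finger="index", segment="dp2")


class TestGraspMatrix:
    def test_contact_at_com_has_zero_moment_block(self):
        G = grasp_matrix([_contact([0.1, 0.2, 0.3])], com_world=np.array([0.1, 0.2, 0.3]))
        np.testing.assert_array_equal(G[3:, :], np.zeros((3, 3)))
        np.testing.assert_array_equal(G[:3, :], np.eye(3))

    def test_moment_rows_reproduce_cross_product(self):
        G = grasp_matrix([_contact([0, 0, 0.1])], com_world=np.zeros(3))
        f = np.array([1.0, 0.0, 0.0])
        np.testing.assert_allclose(G[3:, :] @ f, [0.0, 0.1, 0.0], atol=1e-15)

    def test_two_contacts_give_6x6(self):
        G = grasp_matrix([_contact([0, 0, 0.1]), _contact([0, 0, -0.1])], np.zeros(3))
        assert G.shape == (6, 6)

    def test_skew_identity_on_random_vectors(self, rng):
        for _ in range(10):
            r, f = rng.normal(size=3), rng.normal(size=3)
            np.testing.assert_allclose(skew(r) @ f, np.cross(r, f), atol=1e-15)

    def test_requires_a_contact(self):
        with pytest.raises(ValueError):
            grasp_matrix([], np.zeros(3))


class TestFrictionPyramid:
    def test_twelve_facets_and_axis_strictly_inside(self):
        pyr = friction_pyramid([0, 0, 1], 0.4)
        assert pyr.facet_normals.shape == (12, 3)
        np.testing.assert_allclose(np.linalg.norm(pyr.facet_normals, axis=1), 1.0)
        assert np.all(pyr.facet_normals @ np.array([0, 0, 1.0]) < 0)

    def test_pure_tangential_force_violates_some_facet(self):
        pyr = friction_pyramid([0, 0, 1], 0.4)
        assert not pyr.contains([1.0, 0.0, 0.0])

    def test_edge_ray_activates_exactly_two_adjacent_facets(self):
        mu = 0.4
        n = np.array([0.0, 0.0, 1.0])
        pyr = friction_pyramid(n, mu)
        # reconstruct an edge ray: axis tilted by theta at one of the twelve azimuths
        from precigrip.mechanics import _tangent_basis

        t1, t2 = _tangent_basis(n)
        for h in (0, 5):
            az = 2 * np.pi * h / 12
            edge = n + mu * (np.cos(az) * t1 + np.sin(az) * t2)
            prods = pyr.facet_normals @ edge
            on_facets = np.abs(prods) < 1e-10
            assert on_facets.sum() == 2
            assert np.all(prods[~on_facets] < 0)

    def test_inscribed_cone_membership(self, rng):
        mu = 0.5
        pyr = friction_pyramid([0, 1, 0], mu)
        margin = mu * np.cos(np.pi / 12)
        for _ in range(200):
            t = rng.normal(size=3)
            t[1] = 0.0
            t = t / np.linalg.norm(t) * rng.uniform(0, margin)
            f = np.array([0, 1.0, 0]) + t
            assert pyr.contains(f, tol=1e-12)

    def test_pyramid_feasible_implies_exact_cone_feasible(self, rng):
        mu = 0.35
        n = np.array([1.0, 2.0, -0.5])
        n /= np.linalg.norm(n)
        pyr = friction_pyramid(n, mu)
        count = 0
        for _ in range(2000):
            f = rng.normal(size=3)
            if pyr.contains(f, tol=0.0):
                count += 1
                fn = f @ n
                ft = np.linalg.norm(f - fn * n)
                assert fn > 0 and ft <= mu * fn + 1e-12
        assert count > 30  # the sampler actually exercised the pyramid

    def test_frictionless_pyramid_pins_force_to_the_normal_ray(self):
        pyr = friction_pyramid([0, 0, 1], 0.0)
        assert pyr.contains([0, 0, 2.0], tol=1e-12)
        assert not pyr.contains([0.01, 0, 1.0])

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            friction_pyramid([0, 0, 0], 0.4)
        with pytest.raises(ValueError):
            friction_pyramid([0, 0, 1], -0.1)


class TestSoftContactPair:
    def test_offsets_are_two_millimeters_and_symmetric(self):
        c1, c2 = soft_contact_pair([0.1, 0, 0.02], [0, 0, 1], [1, 1, 0])
        centroid = np.array([0.1, 0, 0.02])
        assert np.linalg.norm(c1.point - centroid) == pytest.approx(0.002)
        assert np.linalg.norm(c2.point - centroid) == pytest.approx(0.002)
        np.testing.assert_allclose((c1.point + c2.point) / 2, centroid, atol=1e-15)
        assert abs((c1.point - centroid) @ np.array([0, 0, 1.0])) < 1e-15

    def test_opposite_tangential_forces_make_a_torsional_couple(self):
        c1, c2 = soft_contact_pair([0, 0, 0], [0, 0, 1], [0, 1, 0])
        F = 2.5
        t = np.array([F, 0, 0]) * np.sign((c1.point)[1] or 1)
        m = np.cross(c1.point, [F, 0, 0]) + np.cross(c2.point, [-F, 0, 0])
        # couple arm is 4 mm: |M| = 0.004 * F about the contact normal
        np.testing.assert_allclose(m, [0, 0, -0.004 * F], atol=1e-15)

    def test_degenerate_lateral_axis_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            soft_contact_pair([0, 0, 0], [0, 0, 1], [0, 0, 2])


class TestFacetMatrix:
    def test_block_dimensions_and_zero_off_blocks(self):
        pyrs = [friction_pyramid([0, 0, 1], 0.4), friction_pyramid([0, 1, 0], 0.4)]
        N = assemble_facet_matrix(pyrs)
        assert N.shape == (24, 6)
        assert np.all(N[:12, 3:] == 0.0)
        assert np.all(N[12:, :3] == 0.0)

    def test_stack_equivalent_to_per_contact_checks(self, rng):
        pyrs = [friction_pyramid([0, 0, 1], 0.3), friction_pyramid([1, 0, 0], 0.6)]
        N = assemble_facet_matrix(pyrs)
        for _ in range(300):
            f = rng.normal(size=6)
            stacked = bool(np.all(N @ f <= 1e-12))
            per_contact = pyrs[0].contains(f[:3]) and pyrs[1].contains(f[3:])
            assert stacked == per_contact


class TestSensingDevice:
    def test_fixture_geometry_and_mass(self, device):
        assert device.mass == pytest.approx(0.1984)
        assert device.mu_actual == pytest.approx(0.8)
        assert len(device.surfaces) == 2
        for s in device.surfaces:
            dims = sorted([2 * s.half_u, 2 * s.half_v])
            assert dims[0] == pytest.approx(0.020) and dims[1] == pytest.approx(0.049)
        # plates are parallel, inward normals opposed
        a, b = device.surfaces
        assert a.normal @ b.normal == pytest.approx(-1.0)

    def test_signed_distance_and_gradient(self, device, rng):
        pts = np.array([[0, 0, 0], [0.03, 0, 0], [0.02, 0, 0]])
        d = device.signed_distance(pts)
        assert d[0] < 0 and d[1] == pytest.approx(0.01) and d[2] == pytest.approx(0.0)
        # gradient vs central differences at generic exterior points
        pts = rng.normal(scale=0.05, size=(20, 3))
        g = device.distance_gradient(pts)
        h = 1e-7
        for k in range(3):
            dp = pts.copy(); dp[:, k] += h
            dm = pts.copy(); dm[:, k] -= h
            fd = (device.signed_distance(dp) - device.signed_distance(dm)) / (2 * h)
            np.testing.assert_allclose(g[:, k], fd, atol=1e-6)

    def test_object_config_round_trip(self, device, tmp_path):
        from precigrip.mechanics import load_object_config, save_object_config

        path = tmp_path / "device.yaml"
        save_object_config(device, path)
        loaded = load_object_config(path)
        assert loaded.mass == pytest.approx(device.mass)
        pts = np.array([[0.011, 0.003, -0.002]])
        np.testing.assert_allclose(
            loaded.signed_distance(pts), device.signed_distance(pts), atol=1e-12
        )


# ---------------------------------------------------------------------------
# property-based checks
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st

finite3 = st.lists(st.floats(-1.0, 1.0), min_size=3, max_size=3).map(np.array)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(normal=finite3, mu=st.floats(0.0, 2.0))
def test_pyramid_axis_always_feasible(normal, mu):
    if np.linalg.norm(normal) < 1e-6:
        return
    pyr = friction_pyramid(normal, mu)
    n = normal / np.linalg.norm(normal)
    assert pyr.contains(n, tol=1e-12)
    # membership is scale-invariant along the ray
    assert pyr.contains(7.3 * n, tol=1e-11)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(centroid=finite3, normal=finite3, lateral=finite3)
def test_soft_pair_geometry_properties(centroid, normal, lateral):
    if np.linalg.norm(normal) < 1e-6:
        return
    n = normal / np.linalg.norm(normal)
    lat_in_plane = lateral - (lateral @ n) * n
    if np.linalg.norm(lat_in_plane) < 1e-6:
        return
    c1, c2 = soft_contact_pair(centroid, normal, lateral)
    np.testing.assert_allclose((c1.point + c2.point) / 2, centroid, atol=1e-12)
    assert np.linalg.norm(c1.point - centroid) == pytest.approx(0.002, abs=1e-12)
    assert abs((c1.point - c2.point) @ n) < 1e-12  # offsets lie in the contact plane
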