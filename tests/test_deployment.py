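import math

import numpy as np
import pytest

from fvstent import (
    DeploymentConfig,
    deployed_surface,
    expand,
    init_simplex_tube,
    validate_mesh,
    wall_distance,
)
from fvstent._geom import TriMeshQuery
from fvstent.deployment import PlacementError, STATE_ACTIVE


def brute_force_first_hit(mesh, origin, direction):
    """Independent all-triangle ray scan (plane + cross-product side tests)."""
    best = np.inf
    for tri in mesh.triangles():
        a, b, c = tri
        n = np.cross(b - a, c - a)
        denom = n @ direction
        if abs(denom) < 1e-14:
            continue
        t = (n @ (a - origin)) / denom
        if t <= 1e-9:
            continue
        p = origin + t * direction
        if (
            np.cross(b - a, p - a) @ n >= -1e-10
            and np.cross(c - b, p - b) @ n >= -1e-10
            and np.cross(a - c, p - c) @ n >= -1e-10
        ):
            best = min(best, t)
    return best


class TestInit:
    def test_station_count(self, straight_matched):
        _, truth = straight_matched
        cfg = DeploymentConfig(stent_length=23.0, stations_per_mm=2.0)
        tube = init_simplex_tube(truth.centerline, cfg)
        assert tube.stations == 47

    def test_initial_radius_everywhere(self, straight_matched):
        _, truth = straight_matched
        tube = init_simplex_tube(truth.centerline, DeploymentConfig())
        assert np.all(tube.radius == 0.5)

    def test_symmetric_station_arclengths(self, straight_matched):
        _, truth = straight_matched
        tube = init_simplex_tube(truth.centerline, DeploymentConfig())
        mid = truth.centerline.length / 2
        np.testing.assert_allclose(
            tube.station_arclength - mid, -(tube.station_arclength[::-1] - mid),
            atol=1e-9,
        )

    def test_too_long_stent_rejected(self, straight_matched):
        _, truth = straight_matched
        with pytest.raises(PlacementError):
            init_simplex_tube(truth.centerline, DeploymentConfig(stent_length=40.0))

    def test_simplex_three_neighbors(self, straight_matched):
        """The neighbor rule references exactly 3 lattice sites per vertex."""
        _, truth = straight_matched
        tube = init_simplex_tube(truth.centerline, DeploymentConfig())
        r = np.arange(tube.stations * tube.rings, dtype=float).reshape(
            tube.stations, tube.rings
        )
        tube2 = init_simplex_tube(truth.centerline, DeploymentConfig())
        tube2.radius = r
        mean = tube2.neighbor_mean_radius()
        s, j = 5, 7  # interior vertex
        left, right = r[s, j - 1], r[s, (j + 1) % tube.rings]
        axial = r[s + 1, j] if (s + j) % 2 == 0 else r[s - 1, j]
        assert mean[s, j] == pytest.approx((left + right + axial) / 3)


class TestExpansion:
    def test_matched_tube_apposition(self, deployed_matched):
        tube, mesh, _ = deployed_matched
        cfg = tube.config
        assert tube.converged
        from fvstent.metrics import apposition_gap, diameter_profile

        gap = apposition_gap(tube, mesh)
        assert gap["max"] <= cfg.contact_tolerance + 1e-9
        assert np.all(tube.state != STATE_ACTIVE)
        prof = diameter_profile(tube)
        assert prof.mean() == pytest.approx(4.5, abs=2 * cfg.contact_tolerance)

    def test_oversized_tube_caps_at_free_diameter(self, deployed_oversized):
        tube, mesh, _ = deployed_oversized
        from fvstent.metrics import diameter_profile

        assert diameter_profile(tube).max() == pytest.approx(4.5, rel=0.01)
        assert tube.radius.max() <= 4.5 / 2 + 1e-9

    def test_phase1_geometric_bound(self, deployed_matched):
        tube, _, _ = deployed_matched
        cfg = tube.config
        bound = math.ceil(
            math.log(2.25 / cfg.initial_radius) / math.log(cfg.growth_factor)
        )
        assert tube.phase1_iterations <= bound

    def test_monotone_expansion(self, straight_matched):
        mesh, truth = straight_matched
        cfg = DeploymentConfig(max_iterations=3)
        tube = init_simplex_tube(truth.centerline, cfg)
        prev = tube.radius.copy()
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tube = expand(tube, mesh, cfg, debug_checks=True)
        assert np.all(tube.radius >= prev - 1e-15)

    def test_no_wall_penetration(self, deployed_matched):
        tube, mesh, _ = deployed_matched
        query = TriMeshQuery(mesh)
        verts = tube.vertices().reshape(-1, 3)
        assert np.all(query.contains(verts[::7]))

    def test_deterministic(self, straight_matched, deployed_matched):
        mesh, truth = straight_matched
        ref, _, _ = deployed_matched
        cfg = DeploymentConfig()
        tube = expand(init_simplex_tube(truth.centerline, cfg), mesh, cfg)
        np.testing.assert_array_equal(tube.radius, ref.radius)

    def test_length_fixed_no_foreshortening(self, deployed_matched):
        tube, _, _ = deployed_matched
        span = tube.station_arclength[-1] - tube.station_arclength[0]
        assert span == pytest.approx(23.0, abs=1e-12)

    def test_non_watertight_vessel_rejected(self, straight_matched):
        from fvstent import SurfaceMesh

        mesh, truth = straight_matched
        holed = SurfaceMesh(mesh.vertices, mesh.faces[1:])
        cfg = DeploymentConfig()
        with pytest.raises(ValueError):
            expand(init_simplex_tube(truth.centerline, cfg), holed, cfg)

    def test_json_round_trip(self, deployed_matched):
        from fvstent import SimplexTube

        tube, _, _ = deployed_matched
        back = SimplexTube.from_json(tube.to_json())
        np.testing.assert_array_equal(back.radius, tube.radius)
        assert back.config == tube.config


class TestWallDistance:
    def test_axis_point_radial(self, straight_matched):
        mesh, _ = straight_matched
        d = wall_distance([0, 0, 15.0], [1.0, 0, 0], mesh)
        assert d == pytest.approx(2.25, abs=0.01)

    def test_off_axis_point(self, straight_matched):
        mesh, _ = straight_matched
        d = wall_distance([1.0, 0, 15.0], [1.0, 0, 0], mesh)
        assert d == pytest.approx(1.25, abs=0.01)

    def test_outside_point_rejected(self, straight_matched):
        mesh, _ = straight_matched
        with pytest.raises(ValueError):
            wall_distance([10.0, 0, 15.0], [1.0, 0, 0], mesh)

    def test_brute_force_oracle_agreement(self, straight_matched):
        mesh, _ = straight_matched
        query = TriMeshQuery(mesh)
        rng = np.random.default_rng(42)
        for _ in range(100):
            origin = np.array(
                [rng.uniform(-1.5, 1.5), rng.uniform(-1.5, 1.5), rng.uniform(2, 28)]
            )
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            fast = query.first_hit(origin, d, search_radius=4.25)
            slow = brute_force_first_hit(mesh, origin, d)
            assert fast == pytest.approx(slow, abs=1e-9)


class TestDeployedSurface:
    def test_triangle_count(self, deployed_matched):
        tube, _, _ = deployed_matched
        surf = deployed_surface(tube)
        assert surf.n_faces == tube.rings * (tube.stations - 1) * 2 == 2944

    def test_vertices_coincide(self, deployed_matched):
        tube, _, _ = deployed_matched
        surf = deployed_surface(tube)
        np.testing.assert_array_equal(
            surf.vertices, tube.vertices().reshape(-1, 3)
        )

    def test_open_cylinder_boundary(self, deployed_matched):
        tube, _, _ = deployed_matched
        report = validate_mesh(deployed_surface(tube))
        # the only irregular edges are the 2*rings boundary edges at the ends
        assert report.n_nonmanifold_edges == 2 * tube.rings
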