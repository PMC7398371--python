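import math

import numpy as np
import pytest

from fvstent import (
    Centerline,
    DeploymentConfig,
    SurfaceMesh,
    braid_angle_design,
    expand,
    generate_wire_paths,
    init_simplex_tube,
    sweep_wires,
)
from fvstent.metrics import (
    IntegrityError,
    apposition_gap,
    axial_length,
    diameter_profile,
    measure_braid_angle,
    metal_coverage,
    morphometrics,
    pore_density,
)


def mc_coverage_oracle(model, tube, n_points=100_000, seed=0):
    """Independent Monte-Carlo estimate of unrolled-plane coverage."""
    L = float(tube.station_arclength[-1] - tube.station_arclength[0])
    r_mean = float(tube.radius.mean())
    C = 2 * math.pi * r_mean
    half_w = model.device["wire_diameter"] / 2.0
    rng = np.random.default_rng(seed)
    pts = rng.uniform([0, 0], [L, C], size=(n_points, 2))
    covered = np.zeros(n_points, dtype=bool)
    for w in model.wires:
        x = w.param_t * L
        y = w.param_theta * r_mean
        for k in range(int(np.floor(y.min() / C)) - 1, int(np.ceil(y.max() / C)) + 2):
            ys = y - k * C
            for i in range(len(x) - 1):
                lo_y, hi_y = sorted((ys[i], ys[i + 1]))
                if hi_y < -half_w or lo_y > C + half_w:
                    continue
                sel = ~covered
                if not np.any(sel):
                    return 1.0
                p = pts[sel]
                a = np.array([x[i], ys[i]])
                b = np.array([x[i + 1], ys[i + 1]])
                ab = b - a
                t = np.clip((p - a) @ ab / (ab @ ab), 0.0, 1.0)
                d = np.linalg.norm(p - (a + t[:, None] * ab), axis=1)
                idx = np.flatnonzero(sel)
                covered[idx[d <= half_w]] = True
    return covered.mean()


class TestProfileAndGap:
    def test_matched_profile(self, deployed_matched):
        tube, _, _ = deployed_matched
        prof = diameter_profile(tube)
        tol = tube.config.contact_tolerance
        assert np.all(np.abs(prof - 4.5) <= 2 * tol + 0.01)

    def test_oversized_profile_capped(self, deployed_oversized):
        tube, _, _ = deployed_oversized
        assert np.all(diameter_profile(tube) <= 4.5 + 1e-6)

    def test_unexpanded_profile(self, straight_matched):
        _, truth = straight_matched
        tube = init_simplex_tube(truth.centerline, DeploymentConfig())
        assert np.allclose(diameter_profile(tube), 1.0)

    def test_unexpanded_gap(self, straight_matched):
        mesh, truth = straight_matched
        tube = init_simplex_tube(truth.centerline, DeploymentConfig())
        gap = apposition_gap(tube, mesh)
        assert gap["mean"] == pytest.approx(2.25 - 0.5, abs=0.02)

    def test_matched_gap_within_tolerance(self, deployed_matched):
        tube, mesh, _ = deployed_matched
        gap = apposition_gap(tube, mesh)
        assert gap["max"] <= tube.config.contact_tolerance + 1e-9
        assert gap["mean"] >= 0.0

    def test_oversized_cap_gap(self, deployed_oversized):
        tube, mesh, _ = deployed_oversized
        gap = apposition_gap(tube, mesh)
        assert gap["max"] == pytest.approx(3.0 - 2.25, abs=0.02)

    def test_penetration_detected(self, deployed_matched):
        import dataclasses

        tube, mesh, _ = deployed_matched
        bad = dataclasses.replace(tube, radius=tube.radius + 1.0)
        with pytest.raises(IntegrityError):
            apposition_gap(bad, mesh)


class TestAxialLength:
    def test_configured_23(self, deployed_matched):
        tube, _, _ = deployed_matched
        assert axial_length(tube) == pytest.approx(23.0, abs=1e-12)

    def test_configured_10(self, straight_matched):
        _, truth = straight_matched
        tube = init_simplex_tube(truth.centerline, DeploymentConfig(stent_length=10.0))
        assert axial_length(tube) == pytest.approx(10.0, abs=1e-12)

    def test_invariant_under_expansion(self, straight_matched, deployed_matched):
        _, truth = straight_matched
        before = init_simplex_tube(truth.centerline, DeploymentConfig())
        after, _, _ = deployed_matched
        assert axial_length(before) == axial_length(after)


class TestCoverage:
    def test_zero_wires(self, deployed_matched):
        from fvstent.braid import StentModel
        from fvstent.mesh_io import SurfaceMesh as SM

        tube, _, _ = deployed_matched
        empty = StentModel(
            wires=[],
            swept=SM(np.zeros((3, 3)), np.zeros((0, 3), dtype=int)),
            device={"wire_diameter": 0.06},
        )
        assert metal_coverage(empty, tube) == 0.0

    def test_single_generator_strip(self, deployed_matched):
        """One straight axial wire covers ~w/C of the unrolled plane."""
        tube, _, _ = deployed_matched
        from fvstent.braid import StentModel, WireCurve

        S = tube.stations
        t = np.linspace(0, 1, S)
        w = WireCurve(
            0, "cw", tube.vertices()[:, 0, :], wire_diameter=0.2,
            theta0=1.0, signed_turns=0.0, param_t=t, param_theta=np.full(S, 1.0),
        )
        model = StentModel(wires=[w], swept=None, device={"wire_diameter": 0.2})
        C = 2 * math.pi * tube.radius.mean()
        cov = metal_coverage(model, tube, raster_cells=200_000)
        assert cov == pytest.approx(0.2 / C, rel=0.05)

    def test_against_monte_carlo_oracle(self, stent_model_matched):
        model, tube, _, _ = stent_model_matched
        cov = metal_coverage(model, tube)
        mc = mc_coverage_oracle(model, tube, n_points=100_000, seed=7)
        assert abs(cov - mc) < 0.01

    def test_monotone_in_wire_diameter(self, deployed_matched):
        tube, _, _ = deployed_matched
        wires = generate_wire_paths(tube, n_wires=16)
        covs = [
            metal_coverage(
                sweep_wires(wires, wire_diameter=d), tube, raster_cells=40_000
            )
            for d in (0.03, 0.06, 0.12)
        ]
        assert covs[0] < covs[1] < covs[2]

    def test_monotone_in_wire_count(self, deployed_matched):
        tube, _, _ = deployed_matched
        covs = []
        for n in (8, 16, 32):
            model = sweep_wires(generate_wire_paths(tube, n_wires=n))
            covs.append(metal_coverage(model, tube, raster_cells=40_000))
        assert covs[0] < covs[1] < covs[2]

    def test_deterministic(self, stent_model_matched):
        model, tube, _, _ = stent_model_matched
        assert metal_coverage(model, tube) == metal_coverage(model, tube)

    def test_low_resolution_warns(self, stent_model_matched):
        model, tube, _, _ = stent_model_matched
        with pytest.warns(UserWarning):
            metal_coverage(model, tube, raster_cells=1000)


@pytest.fixture(scope="module")
def tight_deployment(straight_matched):
    mesh, truth = straight_matched
    cfg = DeploymentConfig(contact_tolerance=0.01)
    return expand(init_simplex_tube(truth.centerline, cfg), mesh, cfg), truth


class TestBraidAngle:
    def test_designed_45(self, tight_deployment):
        tube, truth = tight_deployment
        turns = braid_angle_design(4.5, 23.0, 45.0)
        model = sweep_wires(generate_wire_paths(tube, 16, turns=turns))
        cl = Centerline.from_points(tube.centers, arclength=tube.station_arclength)
        assert measure_braid_angle(model, cl) == pytest.approx(45.0, abs=0.5)

    def test_handedness_symmetry(self, tight_deployment):
        tube, truth = tight_deployment
        model = sweep_wires(generate_wire_paths(tube, 16))
        cl = Centerline.from_points(tube.centers, arclength=tube.station_arclength)
        cw = measure_braid_angle(model, cl, handedness="cw")
        ccw = measure_braid_angle(model, cl, handedness="ccw")
        assert abs(cw - ccw) < 0.5

    def test_pore_density_positive(self, stent_model_matched):
        model, tube, _, _ = stent_model_matched
        assert pore_density(model, tube) > 0


class TestMorphometrics:
    def test_hemisphere_height(self):
        """UV hemisphere of radius r sitting on z=0: height exactly r."""
        r = 3.0
        n_th, n_ph = 24, 12
        th = np.linspace(0, 2 * np.pi, n_th, endpoint=False)
        ph = np.linspace(0, np.pi / 2, n_ph)
        verts = [[0, 0, r]]
        for p in ph[1:]:
            for t in th:
                verts.append(
                    [r * math.sin(p) * math.cos(t), r * math.sin(p) * math.sin(t),
                     r * math.cos(p)]
                )
        verts = np.asarray(verts)
        faces = []
        for t in range(n_th):
            faces.append([0, 1 + t, 1 + (t + 1) % n_th])
        for row in range(n_ph - 2):
            base = 1 + row * n_th
            nxt = base + n_th
            for t in range(n_th):
                a, b = base + t, base + (t + 1) % n_th
                c, d = nxt + (t + 1) % n_th, nxt + t
                faces.append([a, b, c])
                faces.append([a, c, d])
        mesh = SurfaceMesh(verts, np.asarray(faces))
        m = morphometrics(mesh, (np.zeros(3), np.array([0, 0, 1.0])))
        assert m["dome_height"] == pytest.approx(r, abs=1e-12)
        assert m["neck_width"] == pytest.approx(2 * r, rel=0.02)

    def test_paper_phantom(self, paper_phantom):
        mesh, truth = paper_phantom
        m = morphometrics(mesh, truth.neck_plane)
        assert m["neck_width"] == pytest.approx(12.27, rel=0.02)
        assert m["dome_height"] == pytest.approx(9.35, rel=0.02)

    def test_plane_missing_mesh(self, paper_phantom):
        mesh, truth = paper_phantom
        point, normal = truth.neck_plane
        with pytest.raises(ValueError):
            morphometrics(mesh, (point + 100 * normal, normal))

    def test_does_not_mutate(self, paper_phantom):
        mesh, truth = paper_phantom
        before = mesh.vertices.copy()
        morphometrics(mesh, truth.neck_plane)
        np.testing.assert_array_equal(mesh.vertices, before)
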