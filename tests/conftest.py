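"""Shared fixtures: phantoms and (expensive) deployments are session-scoped."""

import math

import numpy as np
import pytest

from fvstent import (
    DeploymentConfig,
    PhantomSpec,
    expand,
    init_simplex_tube,
    make_curved_tube,
    make_sidewall_aneurysm,
    make_straight_tube,
    paper_phantom_preset,
)


def build_icosphere(radius: float = 1.0, subdivisions: int = 2):
    """Subdivided icosahedron: (vertices, faces). Independent test geometry."""
    t = (1.0 + math.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=float,
    )
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [v / np.linalg.norm(v) for v in verts]
    cache: dict[tuple[int, int], int] = {}

    def midpoint(a, b):
        key = (min(a, b), max(a, b))
        if key not in cache:
            m = verts[a] + verts[b]
            verts.append(m / np.linalg.norm(m))
            cache[key] = len(verts) - 1
        return cache[key]

    for _ in range(subdivisions):
        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    return np.asarray(verts) * radius, np.asarray(faces, dtype=np.int64)


@pytest.fixture(scope="session")
def straight_matched():
    """d=4.5 mm, L=30 mm straight tube with analytic truth."""
    return make_straight_tube(
        PhantomSpec(tube_diameter=4.5, tube_length=30.0, mesh_resolution=0.3)
    )


@pytest.fixture(scope="session")
def straight_oversized():
    """d=6.0 mm straight tube: free-diameter cap territory."""
    return make_straight_tube(
        PhantomSpec(tube_diameter=6.0, tube_length=30.0, mesh_resolution=0.3)
    )


@pytest.fixture(scope="session")
def curved_tube():
    """bend radius 10 mm, 90 degrees, d=4.5 mm."""
    return make_curved_tube(
        PhantomSpec(
            tube_diameter=4.5, tube_length=0.0, bend_radius=10.0, bend_angle=90.0,
            mesh_resolution=0.3,
        )
    )


@pytest.fixture(scope="session")
def paper_phantom():
    spec = paper_phantom_preset()
    return make_sidewall_aneurysm(spec)


@pytest.fixture(scope="session")
def deployed_matched(straight_matched):
    mesh, truth = straight_matched
    cfg = DeploymentConfig()
    tube = expand(init_simplex_tube(truth.centerline, cfg), mesh, cfg)
    return tube, mesh, truth


@pytest.fixture(scope="session")
def deployed_oversized(straight_oversized):
    mesh, truth = straight_oversized
    cfg = DeploymentConfig()
    tube = expand(init_simplex_tube(truth.centerline, cfg), mesh, cfg)
    return tube, mesh, truth


@pytest.fixture(scope="session")
def stent_model_matched(deployed_matched):
    from fvstent import generate_wire_paths, sweep_wires

    tube, mesh, truth = deployed_matched
    wires = generate_wire_paths(tube, n_wires=16)
    return sweep_wires(wires), tube, mesh, truth
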