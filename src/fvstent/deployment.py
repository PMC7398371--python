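"""Virtual stent deployment: cylindrical simplex tube + adaptive expansion.

The device surface is a (stations x rings) lattice swept along
rotation-minimizing centerline frames.  Expansion is kinematic and
deterministic, in two phases:

* phase 1 (adaptive): uniform multiplicative radius growth until some
  vertex's radial wall distance is no larger than its next increment —
  a geometric-growth bound on the iteration count;
* phase 2 (per-vertex): each active vertex advances radially by
  ``min(wall_distance - contact_tolerance, r*(growth_factor-1))``, then a
  tangential Laplacian pass regularizes the non-contacted front.  A vertex
  freezes on contact (gap <= tolerance) or at the free-radius cap.

Radial coordinates are clamped monotone non-decreasing and never exceed
``min(wall distance, free_diameter/2)``, so non-penetration holds by
construction.  Axial station arclengths stay fixed on the centerline:
foreshortening is deliberately neglected.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings

import numpy as np

from ._geom import TriMeshQuery
from .centerline import Centerline
from .mesh_io import SurfaceMesh, validate_mesh

__all__ = [
    "DeploymentConfig",
    "SimplexTube",
    "init_simplex_tube",
    "expand",
    "wall_distance",
    "deployed_surface",
    "PlacementError",
    "ConvergenceWarning",
]

STATE_ACTIVE = 0
STATE_CONTACTED = 1
STATE_CAPPED = 2


class PlacementError(ValueError):
    """Stent does not fit on the available centerline."""


class ConvergenceWarning(UserWarning):
    pass


@dataclasses.dataclass
class DeploymentConfig:
    stent_length: float = 23.0
    free_diameter: float = 4.5
    initial_radius: float = 0.5
    growth_factor: float = 1.3
    contact_tolerance: float = 0.05
    smoothing_weight: float = 0.3
    max_iterations: int = 500
    rings: int = 32
    stations_per_mm: float = 2.0

    def validate(self) -> None:
        if self.initial_radius >= self.free_diameter / 2:
            raise ValueError("initial_radius must be below free_diameter/2")
        if self.contact_tolerance <= 0:
            raise ValueError("contact_tolerance must be positive")
        if self.growth_factor <= 1:
            raise ValueError("growth_factor must exceed 1")
        if not (0.0 <= self.smoothing_weight <= 1.0):
            raise ValueError("smoothing_weight must be in [0, 1]")
        if self.rings < 3 or self.stent_length <= 0 or self.stations_per_mm <= 0:
            raise ValueError("invalid lattice parameters")


@dataclasses.dataclass
class SimplexTube:
    """Deformable device lattice; geometry is (radius, fixed angle) per vertex."""

    centers: np.ndarray        # (S, 3) centerline points per station
    frame_normal: np.ndarray   # (S, 3)
    frame_binormal: np.ndarray # (S, 3)
    theta: np.ndarray          # (R,) ring angles
    radius: np.ndarray         # (S, R) radial coordinate per vertex
    state: np.ndarray          # (S, R) int: 0 active, 1 contacted, 2 capped
    station_arclength: np.ndarray  # (S,)
    cap_radius: float
    config: DeploymentConfig
    phase1_iterations: int = 0
    iterations: int = 0
    converged: bool = False
    expanded: bool = False

    @property
    def stations(self) -> int:
        return len(self.centers)

    @property
    def rings(self) -> int:
        return len(self.theta)

    def radial_directions(self) -> np.ndarray:
        """(S, R, 3) outward unit direction for every vertex."""
        cos_t = np.cos(self.theta)[None, :, None]
        sin_t = np.sin(self.theta)[None, :, None]
        return cos_t * self.frame_normal[:, None, :] + sin_t * self.frame_binormal[:, None, :]

    def vertices(self) -> np.ndarray:
        """(S, R, 3) vertex positions."""
        return self.centers[:, None, :] + self.radius[..., None] * self.radial_directions()

    def to_json(self) -> str:
        d = {
            "centers": self.centers.tolist(),
            "frame_normal": self.frame_normal.tolist(),
            "frame_binormal": self.frame_binormal.tolist(),
            "theta": self.theta.tolist(),
            "radius": self.radius.tolist(),
            "state": self.state.tolist(),
            "station_arclength": self.station_arclength.tolist(),
            "cap_radius": self.cap_radius,
            "config": dataclasses.asdict(self.config),
            "phase1_iterations": self.phase1_iterations,
            "iterations": self.iterations,
            "converged": self.converged,
            "expanded": self.expanded,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "SimplexTube":
        d = json.loads(text)
        return cls(
            centers=np.asarray(d["centers"]),
            frame_normal=np.asarray(d["frame_normal"]),
            frame_binormal=np.asarray(d["frame_binormal"]),
            theta=np.asarray(d["theta"]),
            radius=np.asarray(d["radius"]),
            state=np.asarray(d["state"], dtype=np.int8),
            station_arclength=np.asarray(d["station_arclength"]),
            cap_radius=d["cap_radius"],
            config=DeploymentConfig(**d["config"]),
            phase1_iterations=d["phase1_iterations"],
            iterations=d["iterations"],
            converged=d["converged"],
            expanded=d["expanded"],
        )

    def neighbor_mean_radius(self) -> np.ndarray:
        """Mean radius over each vertex's simplex neighbors.

        Interior vertices have exactly three: both ring neighbors plus one
        axial neighbor chosen by lattice parity; boundary stations fall
        back to the in-range axial side.
        """
        r = self.radius
        S, R = r.shape
        left = np.roll(r, 1, axis=1)
        right = np.roll(r, -1, axis=1)
        s_idx = np.arange(S)[:, None]
        j_idx = np.arange(R)[None, :]
        axial_off = np.where((s_idx + j_idx) % 2 == 0, 1, -1)
        axial_idx = np.clip(s_idx + axial_off, 0, S - 1)
        axial = r[axial_idx, j_idx]
        return (left + right + axial) / 3.0


def init_simplex_tube(
    cl: Centerline, cfg: DeploymentConfig, center_arclength: float | None = None
) -> SimplexTube:
    """Initialize the device lattice centered at ``center_arclength``."""
    cfg.validate()
    if center_arclength is None:
        center_arclength = cl.length / 2.0
    half = cfg.stent_length / 2.0
    if center_arclength - half < -1e-9 or center_arclength + half > cl.length + 1e-9:
        raise PlacementError(
            f"stent of length {cfg.stent_length} mm does not fit centered at "
            f"s={center_arclength} on a {cl.length:.3f} mm centerline"
        )
    stations = int(math.ceil(cfg.stent_length * cfg.stations_per_mm)) + 1
    s_vals = np.linspace(center_arclength - half, center_arclength + half, stations)
    centers = np.empty((stations, 3))
    normals = np.empty((stations, 3))
    binormals = np.empty((stations, 3))
    for i, s in enumerate(s_vals):
        centers[i] = cl.point_at(s)
        _, n, b = cl.frame_at(s)
        normals[i] = n
        binormals[i] = b
    theta = 2 * math.pi * np.arange(cfg.rings) / cfg.rings
    return SimplexTube(
        centers=centers,
        frame_normal=normals,
        frame_binormal=binormals,
        theta=theta,
        radius=np.full((stations, cfg.rings), cfg.initial_radius),
        state=np.full((stations, cfg.rings), STATE_ACTIVE, dtype=np.int8),
        station_arclength=s_vals,
        cap_radius=cfg.free_diameter / 2.0,
        config=cfg,
    )


def wall_distance(point, direction, vessel: SurfaceMesh) -> float:
    """Distance from an interior point to the first wall hit along a ray."""
    query = TriMeshQuery(vessel)
    point = np.asarray(point, float)
    if not query.contains(point[None])[0]:
        raise ValueError("query point lies outside the lumen")
    return query.first_hit(point, np.asarray(direction, float))


def _station_candidates(tube: SimplexTube, query: TriMeshQuery) -> list[np.ndarray]:
    """Per-station triangle candidate sets (station centers never move)."""
    l_max = tube.cap_radius + 2.0
    radius = l_max + tube.cap_radius + query.max_tri_radius
    return [
        np.asarray(query.tree.query_ball_point(c, radius), dtype=int)
        for c in tube.centers
    ]


def _wall_distances(
    tube: SimplexTube,
    query: TriMeshQuery,
    mask: np.ndarray,
    candidates: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Radial first-hit distances for masked vertices; (S, R) with inf fill."""
    verts = tube.vertices()
    dirs = tube.radial_directions()
    out = np.full(tube.radius.shape, np.inf)
    l_max = tube.cap_radius + 2.0
    for s in range(tube.stations):
        sel = mask[s]
        if not np.any(sel):
            continue
        out[s, sel] = query.first_hits_clustered(
            verts[s, sel],
            dirs[s, sel],
            tube.centers[s],
            l_max,
            candidates=None if candidates is None else candidates[s],
        )
    return out


def expand(tube: SimplexTube, vessel: SurfaceMesh, cfg: DeploymentConfig | None = None,
           debug_checks: bool = False) -> SimplexTube:
    """Expand the lattice until apposition, cap, or the iteration budget."""
    if cfg is None:
        cfg = tube.config
    cfg.validate()
    report = validate_mesh(vessel)
    if not report.watertight:
        raise ValueError("vessel mesh must be watertight for deployment")
    query = TriMeshQuery(vessel)
    candidates = _station_candidates(tube, query)
    tol = cfg.contact_tolerance
    g = cfg.growth_factor
    cap = cfg.free_diameter / 2.0

    # phase 1: uniform multiplicative growth
    while True:
        active = tube.state == STATE_ACTIVE
        d = _wall_distances(tube, query, active, candidates)
        growth = tube.radius * (g - 1.0)
        if np.any(d[active] <= growth[active] + tol):
            break
        new_r = np.minimum(tube.radius * g, cap)
        if np.allclose(new_r, tube.radius):
            break
        tube.radius = new_r
        tube.phase1_iterations += 1
        tube.iterations += 1
        if np.all(tube.radius >= cap - 1e-12):
            tube.state[:] = STATE_CAPPED
            break

    # phase 2: per-vertex advance + tangential regularization
    for _ in range(cfg.max_iterations):
        active = tube.state == STATE_ACTIVE
        if not np.any(active):
            break
        d = _wall_distances(tube, query, active, candidates)

        touching = active & (d <= tol + 1e-9)
        tube.state[touching] = STATE_CONTACTED
        active = tube.state == STATE_ACTIVE
        if not np.any(active):
            tube.iterations += 1
            break

        # advance toward a half-tolerance residual gap so the final gap sits
        # comfortably inside the apposition tolerance despite chordal error
        r_before = tube.radius.copy()
        allowed = np.where(active, r_before + np.maximum(d - 0.5 * tol, 0.0), r_before)
        step = np.minimum(np.maximum(d - 0.5 * tol, 0.0), r_before * (g - 1.0))
        r_moved = np.where(active, r_before + step, r_before)

        if cfg.smoothing_weight > 0:
            smoothed = (1 - cfg.smoothing_weight) * r_moved + (
                cfg.smoothing_weight
                * SimplexTube.neighbor_mean_radius(
                    dataclasses.replace(tube, radius=r_moved)
                )
            )
            r_new = np.where(active, np.maximum(smoothed, r_moved), r_moved)
        else:
            r_new = r_moved
        r_new = np.minimum(np.minimum(r_new, allowed), cap)
        r_new = np.maximum(r_new, r_before)  # monotone by construction
        if debug_checks:
            assert np.all(r_new >= r_before - 1e-15)
        tube.radius = r_new

        capped = (tube.state == STATE_ACTIVE) & (tube.radius >= cap - 1e-12)
        tube.state[capped] = STATE_CAPPED
        tube.iterations += 1

    settled = np.mean(tube.state != STATE_ACTIVE)
    tube.converged = bool(settled >= 0.95)
    if not tube.converged:
        warnings.warn(
            f"expansion stopped with only {settled:.1%} of vertices settled",
            ConvergenceWarning,
        )
    tube.expanded = True
    return tube


def deployed_surface(tube: SimplexTube) -> SurfaceMesh:
    """Open triangulated tube (two triangles per lattice quad, no end caps)."""
    verts = tube.vertices().reshape(-1, 3)
    S, R = tube.stations, tube.rings
    faces = []
    for s in range(S - 1):
        for j in range(R):
            a = s * R + j
            b = s * R + (j + 1) % R
            c = (s + 1) * R + (j + 1) % R
            d = (s + 1) * R + j
            faces.append((a, b, c))
            faces.append((a, c, d))
    return SurfaceMesh(verts, np.asarray(faces), provenance="deployed_simplex_tube")
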