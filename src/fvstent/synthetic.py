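"""Parametric vessel / aneurysm phantoms with analytic ground truth.

Every downstream stage (centerline, deployment, braid, metrics) is tested
against these generators, so each one returns both the surface mesh and a
:class:`PhantomTruth` carrying the exact centerline, the aneurysm neck
plane and the nominal radius profile.

Tubes are built parametrically (lateral vertices exactly on the nominal
radius).  The sidewall-aneurysm phantom is an implicit-surface model — a
smooth-min blend of the tube with an ellipsoidal dome — extracted by
marching cubes, because a trimmed-and-stitched union cannot stay watertight
across arbitrary dome placements.
"""

from __future__ import annotations

import dataclasses
import json
import math

import numpy as np

from .centerline import Centerline
from .mesh_io import SurfaceMesh

__all__ = [
    "AneurysmSpec",
    "PhantomSpec",
    "PhantomTruth",
    "make_straight_tube",
    "make_curved_tube",
    "make_sidewall_aneurysm",
    "paper_phantom_preset",
]

#: the neck plane sits this far (mm) above the tube surface so mesh jitter on
#: the tube top can never be classified as sac
NECK_PLANE_LIFT = 0.3
#: the dome solid is cut this far (mm) below the neck plane so a genuine neck
#: channel opens through the tube wall
DOME_CUT_DEPTH = 0.75
#: smooth-min blending radius (mm) between tube and dome
BLEND_RADIUS = 0.4

MIN_BEND_ANGLE_DEG = 5.0


@dataclasses.dataclass
class AneurysmSpec:
    neck_width: float
    dome_height: float
    dome_width: float
    azimuth: float = 90.0  # degrees around the tube axis; 90 = bend binormal

    def validate(self) -> None:
        if self.neck_width <= 0 or self.dome_height <= 0 or self.dome_width <= 0:
            raise ValueError("aneurysm dimensions must be positive")
        if self.neck_width > self.dome_width + 1e-12:
            raise ValueError("neck_width must not exceed dome_width")


@dataclasses.dataclass
class PhantomSpec:
    tube_diameter: float
    tube_length: float
    bend_radius: float | None = None
    bend_angle: float = 0.0  # degrees
    aneurysm: AneurysmSpec | None = None
    mesh_resolution: float = 0.3
    seed: int = 0
    jitter: float = 0.0  # optional surface noise amplitude (mm), default off

    def validate(self) -> None:
        if self.tube_diameter <= 0:
            raise ValueError("tube_diameter must be positive")
        if self.bend_radius is None and self.tube_length <= 0:
            raise ValueError("tube_length must be positive")
        if self.mesh_resolution <= 0:
            raise ValueError("mesh_resolution must be positive")
        if self.bend_radius is not None:
            if self.bend_radius <= self.tube_diameter / 2:
                raise ValueError("bend_radius must exceed the tube radius")
            if self.bend_angle < MIN_BEND_ANGLE_DEG:
                raise ValueError(
                    f"bend_angle below the {MIN_BEND_ANGLE_DEG} degree floor"
                )
        if self.aneurysm is not None:
            self.aneurysm.validate()


@dataclasses.dataclass
class PhantomTruth:
    centerline: Centerline
    neck_plane: tuple[np.ndarray, np.ndarray] | None  # (point, unit normal)
    nominal_radius_profile: tuple[np.ndarray, np.ndarray]  # (arclength, radius)

    def to_json(self) -> str:
        d = {
            "centerline": {
                "points": self.centerline.points.tolist(),
                "arclength": self.centerline.arclength.tolist(),
                "radius": None
                if self.centerline.radius is None
                else self.centerline.radius.tolist(),
            },
            "neck_plane": None
            if self.neck_plane is None
            else {
                "point": self.neck_plane[0].tolist(),
                "normal": self.neck_plane[1].tolist(),
            },
            "nominal_radius_profile": {
                "arclength": self.nominal_radius_profile[0].tolist(),
                "radius": self.nominal_radius_profile[1].tolist(),
            },
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PhantomTruth":
        d = json.loads(text)
        cl = Centerline.from_points(
            np.asarray(d["centerline"]["points"]),
            radius=None
            if d["centerline"]["radius"] is None
            else np.asarray(d["centerline"]["radius"]),
            arclength=np.asarray(d["centerline"]["arclength"]),
        )
        plane = None
        if d["neck_plane"] is not None:
            plane = (
                np.asarray(d["neck_plane"]["point"]),
                np.asarray(d["neck_plane"]["normal"]),
            )
        prof = (
            np.asarray(d["nominal_radius_profile"]["arclength"]),
            np.asarray(d["nominal_radius_profile"]["radius"]),
        )
        return cls(cl, plane, prof)


def _orient_outward(mesh: SurfaceMesh) -> SurfaceMesh:
    if mesh.signed_volume() < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()
    return mesh


def _grid_tube(rings: np.ndarray, cap_centers: tuple[np.ndarray, np.ndarray],
               provenance: str) -> SurfaceMesh:
    """Close a (stations, n_circ, 3) ring lattice with end-cap fans."""
    s, n, _ = rings.shape
    verts = [rings.reshape(-1, 3), cap_centers[0][None], cap_centers[1][None]]
    vertices = np.concatenate(verts)
    i0, i1 = s * n, s * n + 1
    faces = []
    for i in range(s - 1):
        for j in range(n):
            a = i * n + j
            b = i * n + (j + 1) % n
            c = (i + 1) * n + (j + 1) % n
            d = (i + 1) * n + j
            faces.append((a, b, c))
            faces.append((a, c, d))
    for j in range(n):  # start cap
        faces.append((i0, (j + 1) % n, j))
    base = (s - 1) * n
    for j in range(n):  # end cap
        faces.append((i1, base + j, base + (j + 1) % n))
    return _orient_outward(SurfaceMesh(vertices, np.asarray(faces), provenance))


def _apply_jitter(mesh: SurfaceMesh, spec: PhantomSpec) -> SurfaceMesh:
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        mesh.vertices = mesh.vertices + rng.normal(
            scale=spec.jitter, size=mesh.vertices.shape
        )
    return mesh


def make_straight_tube(spec: PhantomSpec) -> tuple[SurfaceMesh, PhantomTruth]:
    """Capped straight cylinder along +z, lateral vertices exactly on radius."""
    spec.validate()
    if spec.aneurysm is not None:
        raise ValueError("straight tube generator takes no aneurysm block")
    r = spec.tube_diameter / 2.0
    res = spec.mesh_resolution
    n_circ = max(12, int(round(2 * math.pi * r / res)))
    n_axial = max(2, int(round(spec.tube_length / res)) + 1)
    z = np.linspace(0.0, spec.tube_length, n_axial)
    theta = 2 * math.pi * np.arange(n_circ) / n_circ
    ring = np.column_stack([r * np.cos(theta), r * np.sin(theta), np.zeros(n_circ)])
    rings = ring[None, :, :] + np.array([0.0, 0.0, 1.0])[None, None, :] * z[:, None, None]
    mesh = _grid_tube(
        rings,
        (np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, spec.tube_length])),
        "synthetic:straight_tube",
    )
    mesh = _apply_jitter(mesh, spec)
    pts = np.column_stack([np.zeros(n_axial), np.zeros(n_axial), z])
    cl = Centerline.from_points(pts, radius=np.full(n_axial, r), arclength=z.copy())
    truth = PhantomTruth(cl, None, (z.copy(), np.full(n_axial, r)))
    return mesh, truth


def _arc_geometry(spec: PhantomSpec, n_axial: int):
    """Arc centerline points/frames for a bend in the xy-plane."""
    R = spec.bend_radius
    A = math.radians(spec.bend_angle)
    phi = np.linspace(0.0, A, n_axial)
    centers = np.column_stack([R * np.cos(phi), R * np.sin(phi), np.zeros(n_axial)])
    e_r = np.column_stack([np.cos(phi), np.sin(phi), np.zeros(n_axial)])
    e_z = np.tile(np.array([0.0, 0.0, 1.0]), (n_axial, 1))
    arclength = R * phi
    return centers, e_r, e_z, arclength


def make_curved_tube(spec: PhantomSpec) -> tuple[SurfaceMesh, PhantomTruth]:
    """Torus-segment tube with planar end caps; truth centerline is the arc."""
    spec.validate()
    if spec.bend_radius is None:
        raise ValueError("curved tube requires bend_radius")
    r = spec.tube_diameter / 2.0
    res = spec.mesh_resolution
    arc_len = spec.bend_radius * math.radians(spec.bend_angle)
    n_circ = max(12, int(round(2 * math.pi * r / res)))
    n_axial = max(2, int(round(arc_len / res)) + 1)
    centers, e_r, e_z, arclength = _arc_geometry(spec, n_axial)
    theta = 2 * math.pi * np.arange(n_circ) / n_circ
    rings = (
        centers[:, None, :]
        + r * np.cos(theta)[None, :, None] * e_r[:, None, :]
        + r * np.sin(theta)[None, :, None] * e_z[:, None, :]
    )
    mesh = _grid_tube(rings, (centers[0], centers[-1]), "synthetic:curved_tube")
    mesh = _apply_jitter(mesh, spec)
    cl = Centerline.from_points(
        centers, radius=np.full(n_axial, r), arclength=arclength.copy()
    )
    truth = PhantomTruth(cl, None, (arclength.copy(), np.full(n_axial, r)))
    return mesh, truth


# ---------------------------------------------------------------------------
# implicit aneurysm phantom
# ---------------------------------------------------------------------------

def _smin(a: np.ndarray, b: np.ndarray, k: float) -> np.ndarray:
    """Polynomial smooth minimum (Quilez)."""
    h = np.clip(0.5 + 0.5 * (b - a) / k, 0.0, 1.0)
    return b + (a - b) * h - k * h * (1.0 - h)


def _smax(a: np.ndarray, b: np.ndarray, k: float) -> np.ndarray:
    return -_smin(-a, -b, k)


def _tube_sdf(p: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Capsule-style SDF of the (straight or curved) parent tube."""
    r = spec.tube_diameter / 2.0
    if spec.bend_radius is None:
        z = np.clip(p[:, 2], 0.0, spec.tube_length)
        closest = np.column_stack([np.zeros(len(p)), np.zeros(len(p)), z])
        return np.linalg.norm(p - closest, axis=1) - r
    R = spec.bend_radius
    A = math.radians(spec.bend_angle)
    phi = np.clip(np.arctan2(p[:, 1], p[:, 0]), 0.0, A)
    closest = np.column_stack([R * np.cos(phi), R * np.sin(phi), np.zeros(len(p))])
    return np.linalg.norm(p - closest, axis=1) - r


def _dome_frame(spec: PhantomSpec):
    """Neck-plane point and normal at the tube midpoint for the dome."""
    r = spec.tube_diameter / 2.0
    az = math.radians(spec.aneurysm.azimuth)
    if spec.bend_radius is None:
        mid = np.array([0.0, 0.0, spec.tube_length / 2.0])
        d_hat = np.array([math.cos(az), math.sin(az), 0.0])
    else:
        R = spec.bend_radius
        phi_m = math.radians(spec.bend_angle) / 2.0
        mid = np.array([R * math.cos(phi_m), R * math.sin(phi_m), 0.0])
        e_r = np.array([math.cos(phi_m), math.sin(phi_m), 0.0])
        d_hat = math.cos(az) * e_r + math.sin(az) * np.array([0.0, 0.0, 1.0])
    plane_point = mid + (r + NECK_PLANE_LIFT) * d_hat
    return plane_point, d_hat


def _dome_sdf(p: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Ellipsoid centered on the neck plane, cut below it to open the neck."""
    an = spec.aneurysm
    a = an.dome_width / 2.0
    c = an.dome_height
    plane_point, d_hat = _dome_frame(spec)
    rel = p - plane_point
    w = rel @ d_hat
    rho = np.linalg.norm(rel - np.outer(w, d_hat), axis=1)
    # approximate ellipsoid SDF (Quilez): k0*(k0-1)/k1
    k0 = np.sqrt((rho / a) ** 2 + (w / c) ** 2)
    k1 = np.sqrt((rho / a**2) ** 2 + (w / c**2) ** 2)
    k1 = np.where(k1 < 1e-12, 1e-12, k1)
    f_e = k0 * (k0 - 1.0) / k1
    f_cut = -DOME_CUT_DEPTH - w  # inside where w > -DOME_CUT_DEPTH
    return _smax(f_e, f_cut, 0.2)


def make_sidewall_aneurysm(spec: PhantomSpec) -> tuple[SurfaceMesh, PhantomTruth]:
    """Smooth union of the parent tube with an ellipsoidal dome.

    Degenerates to :func:`make_curved_tube` / :func:`make_straight_tube`
    when no aneurysm block is set.  The implicit blend is sampled on a
    uniform grid at ``mesh_resolution`` and extracted by marching cubes,
    so end caps are rounded rather than planar.
    """
    spec.validate()
    if spec.aneurysm is None:
        if spec.bend_radius is None:
            return make_straight_tube(spec)
        return make_curved_tube(spec)
    from skimage.measure import marching_cubes

    an = spec.aneurysm
    tube_len = (
        spec.tube_length
        if spec.bend_radius is None
        else spec.bend_radius * math.radians(spec.bend_angle)
    )
    if an.dome_width >= tube_len:
        raise ValueError("dome would swallow the tube (dome_width >= tube length)")
    if an.dome_height <= NECK_PLANE_LIFT:
        raise ValueError("dome_height too small to clear the neck plane lift")

    r = spec.tube_diameter / 2.0
    plane_point, d_hat = _dome_frame(spec)

    # bounding box of tube union dome, with margin
    if spec.bend_radius is None:
        tube_lo = np.array([-r, -r, -r])
        tube_hi = np.array([r, r, spec.tube_length + r])
    else:
        R, A = spec.bend_radius, math.radians(spec.bend_angle)
        phi = np.linspace(0.0, A, 64)
        pts = np.column_stack([R * np.cos(phi), R * np.sin(phi), np.zeros(64)])
        tube_lo = pts.min(axis=0) - r
        tube_hi = pts.max(axis=0) + r
    ext = max(an.dome_width / 2.0, an.dome_height)
    dome_lo = plane_point - ext
    dome_hi = plane_point + ext
    lo = np.minimum(tube_lo, dome_lo) - 3 * spec.mesh_resolution
    hi = np.maximum(tube_hi, dome_hi) + 3 * spec.mesh_resolution

    h = spec.mesh_resolution
    axes = [np.arange(lo[i], hi[i] + h, h) for i in range(3)]
    grid = np.meshgrid(*axes, indexing="ij")
    p = np.column_stack([g.ravel() for g in grid])
    field = _smin(_tube_sdf(p, spec), _dome_sdf(p, spec), BLEND_RADIUS)
    volume = field.reshape(len(axes[0]), len(axes[1]), len(axes[2]))

    verts, faces, _, _ = marching_cubes(volume, level=0.0, spacing=(h, h, h))
    verts = verts + lo
    mesh = _orient_outward(
        SurfaceMesh(verts, faces.astype(np.int64), "synthetic:sidewall_aneurysm")
    )

    if spec.bend_radius is None:
        n_axial = max(2, int(round(spec.tube_length / h)) + 1)
        z = np.linspace(0.0, spec.tube_length, n_axial)
        cl_pts = np.column_stack([np.zeros(n_axial), np.zeros(n_axial), z])
        s = z.copy()
    else:
        n_axial = max(2, int(round(tube_len / h)) + 1)
        cl_pts, _, _, s = _arc_geometry(spec, n_axial)
    cl = Centerline.from_points(cl_pts, radius=np.full(n_axial, r), arclength=s.copy())
    truth = PhantomTruth(cl, (plane_point, d_hat), (s.copy(), np.full(n_axial, r)))
    return mesh, truth


def paper_phantom_preset() -> PhantomSpec:
    """Curved parent vessel carrying the wide-necked sidewall aneurysm.

    Device-matched 4.5 mm calibre tube; neck width 12.27 mm and dome height
    9.35 mm.  Bend radius/angle are assumptions (no published values) sized
    so a 23 mm stent fits the arc with margin.  Deterministic.
    """
    bend_radius = 20.0
    bend_angle = 80.0
    return PhantomSpec(
        tube_diameter=4.5,
        tube_length=bend_radius * math.radians(bend_angle),
        bend_radius=bend_radius,
        bend_angle=bend_angle,
        aneurysm=AneurysmSpec(
            neck_width=12.27, dome_height=9.35, dome_width=12.27, azimuth=90.0
        ),
        mesh_resolution=0.35,
        seed=0,
    )
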