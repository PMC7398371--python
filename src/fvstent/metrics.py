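"""Deployment-quality and device-geometry metrics.

Desk-scale surrogates for visual deployment checks: diameter profile,
wall-apposition gap, axial length, wire lengths, measured braid angle,
parameter-space metal coverage, pore density, and aneurysm morphometrics.
All metrics are deterministic and never mutate their inputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings

import numpy as np
from scipy.spatial import ConvexHull

from ._geom import TriMeshQuery
from .braid import StentModel, crossing_count
from .centerline import Centerline
from .deployment import SimplexTube
from .mesh_io import SurfaceMesh

__all__ = [
    "DeploymentMetrics",
    "diameter_profile",
    "apposition_gap",
    "axial_length",
    "metal_coverage",
    "pore_density",
    "measure_braid_angle",
    "morphometrics",
    "compute_deployment_metrics",
    "IntegrityError",
]

METRICS_SCHEMA_VERSION = 1
MIN_RASTER_CELLS = 10_000


class IntegrityError(RuntimeError):
    """A stent vertex lies outside the lumen — upstream penetration bug."""


@dataclasses.dataclass
class DeploymentMetrics:
    diameter_profile: list[float]
    mean_diameter: float
    max_diameter: float
    apposition_gap_mean: float
    apposition_gap_max: float
    stent_length_axial: float
    wire_lengths: list[float]
    braid_angle_measured: float
    metal_coverage: float
    pore_density: float

    def to_json(self) -> str:
        d = {"schema_version": METRICS_SCHEMA_VERSION}
        d.update(dataclasses.asdict(self))
        return json.dumps(d, indent=1)


def diameter_profile(tube: SimplexTube) -> np.ndarray:
    """Per-station diameter: twice the ring-mean radial coordinate."""
    return 2.0 * tube.radius.mean(axis=1)


def axial_length(tube: SimplexTube) -> float:
    """Arclength span between first and last stations (no foreshortening)."""
    return float(tube.station_arclength[-1] - tube.station_arclength[0])


def apposition_gap(
    tube: SimplexTube, vessel: SurfaceMesh, check_containment: bool = True
) -> dict:
    """Statistics of the outward radial wall distance over all vertices."""
    query = TriMeshQuery(vessel)
    verts = tube.vertices().reshape(-1, 3)
    dirs = tube.radial_directions().reshape(-1, 3)
    if check_containment and not np.all(query.contains(verts)):
        raise IntegrityError("stent vertex outside the lumen (wall penetration)")
    d = query.first_hits(verts, dirs, search_radius=2 * tube.cap_radius + 2.0)
    return {"mean": float(np.mean(d)), "max": float(np.max(d))}


# ---------------------------------------------------------------------------
# parameter-space coverage
# ---------------------------------------------------------------------------

def _unrolled_segments(model: StentModel, tube: SimplexTube):
    """Wire polylines in the unrolled (arclength, r_mean*theta) plane.

    Returns (segments (M,2,2), plane length L, plane width C); segments are
    tiled at -C, 0, +C in y so periodic wrap needs no special casing.
    """
    L = axial_length(tube)
    r_mean = float(tube.radius.mean())
    C = 2 * math.pi * r_mean
    segs = []
    for w in model.wires:
        if w.param_t is None or w.param_theta is None:
            raise ValueError("wire lacks parameter-space path")
        x = w.param_t * L
        y = w.param_theta * r_mean  # unwrapped; tile copies into [0, C]
        p = np.column_stack([x, y])
        a, b = p[:-1], p[1:]
        k_lo = int(math.floor(y.min() / C)) - 1
        k_hi = int(math.ceil(y.max() / C)) + 1
        for k in range(k_lo, k_hi + 1):
            sa = a - np.array([0.0, k * C])
            sb = b - np.array([0.0, k * C])
            ymin = np.minimum(sa[:, 1], sb[:, 1])
            ymax = np.maximum(sa[:, 1], sb[:, 1])
            keep = (ymax > -1.0) & (ymin < C + 1.0)
            if np.any(keep):
                segs.append(np.stack([sa[keep], sb[keep]], axis=1))
    if not segs:
        return np.zeros((0, 2, 2)), L, C
    return np.concatenate(segs), L, C


def point_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Min distance from each point to one segment ab (vectorized in points)."""
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-18:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def metal_coverage(model: StentModel, tube: SimplexTube, raster_cells: int = 100_000) -> float:
    """Covered-cell fraction of the unrolled stent surface.

    A cell counts as covered when its center lies within wire_diameter/2 of
    any wire path; crossing wires cover a cell once, matching projection.
    """
    if raster_cells < MIN_RASTER_CELLS:
        warnings.warn(
            f"raster_cells={raster_cells} is below {MIN_RASTER_CELLS}; "
            "coverage will be poorly resolved"
        )
    if not model.wires:
        return 0.0
    half_w = model.device["wire_diameter"] / 2.0
    segs, L, C = _unrolled_segments(model, tube)
    ny = max(8, int(round(math.sqrt(raster_cells * C / L))))
    nx = max(8, int(round(raster_cells / ny)))
    dx, dy = L / nx, C / ny
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy
    covered = np.zeros((nx, ny), dtype=bool)
    for a, b in segs:
        lo = np.minimum(a, b) - half_w
        hi = np.maximum(a, b) + half_w
        i0 = max(0, int(math.floor(lo[0] / dx - 0.5)))
        i1 = min(nx - 1, int(math.ceil(hi[0] / dx - 0.5)))
        j0 = max(0, int(math.floor(lo[1] / dy - 0.5)))
        j1 = min(ny - 1, int(math.ceil(hi[1] / dy - 0.5)))
        if i1 < i0 or j1 < j0:
            continue
        gx, gy = np.meshgrid(xs[i0 : i1 + 1], ys[j0 : j1 + 1], indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        close = point_segment_distance(pts, a, b) <= half_w
        covered[i0 : i1 + 1, j0 : j1 + 1] |= close.reshape(gx.shape)
    return float(covered.mean())


def pore_density(model: StentModel, tube: SimplexTube) -> float:
    """Interior-cell estimate: wire crossings per unrolled area (1/mm^2)."""
    L = axial_length(tube)
    C = 2 * math.pi * float(tube.radius.mean())
    n_cross = 0
    for w1 in model.wires:
        for w2 in model.wires:
            if w1.wire_index < w2.wire_index:
                n_cross += crossing_count(w1, w2)
    return n_cross / (L * C)


def measure_braid_angle(model: StentModel, cl: Centerline, handedness: str | None = None) -> float:
    """Mean angle (degrees) between wire segments and the local tangent."""
    angles = []
    for w in model.wires:
        if handedness is not None and w.handedness != handedness:
            continue
        seg = np.diff(w.points, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        mids = 0.5 * (w.points[:-1] + w.points[1:])
        for s, ln, m in zip(seg, seglen, mids):
            if ln < 1e-12:
                continue
            # tangent at the nearest centerline sample
            i = int(np.argmin(np.linalg.norm(cl.points - m, axis=1)))
            t = cl.tangent[i]
            cosang = abs(float(s @ t)) / ln
            angles.append(math.degrees(math.acos(min(1.0, cosang))))
    return float(np.mean(angles)) if angles else 0.0


def morphometrics(mesh: SurfaceMesh, neck_plane) -> dict:
    """Neck width and dome height of an aneurysm mesh given its neck plane.

    Height: max signed distance of sac-side vertices to the plane.  Width:
    largest sac extent parallel to the plane (diameter of the projected
    point set).
    """
    point, normal = (np.asarray(x, float) for x in neck_plane)
    normal = normal / np.linalg.norm(normal)
    signed = (mesh.vertices - point) @ normal
    sac = mesh.vertices[signed > 1e-9]
    if len(sac) < 3:
        raise ValueError("neck plane misses the mesh: no sac-side vertices")
    height = float(signed.max())

    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ normal) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - normal * (ref @ normal)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    proj = np.column_stack([sac @ u, sac @ v])
    try:
        hull_pts = proj[ConvexHull(proj).vertices]
    except Exception:
        hull_pts = proj
    diff = hull_pts[:, None, :] - hull_pts[None, :, :]
    width = float(np.sqrt((diff**2).sum(axis=2)).max())
    return {"neck_width": width, "dome_height": height}


def compute_deployment_metrics(
    tube: SimplexTube,
    vessel: SurfaceMesh,
    model: StentModel,
    cl: Centerline,
    raster_cells: int = 100_000,
    check_containment: bool = True,
) -> DeploymentMetrics:
    prof = diameter_profile(tube)
    gap = apposition_gap(tube, vessel, check_containment=check_containment)
    return DeploymentMetrics(
        diameter_profile=[float(x) for x in prof],
        mean_diameter=float(prof.mean()),
        max_diameter=float(prof.max()),
        apposition_gap_mean=gap["mean"],
        apposition_gap_max=gap["max"],
        stent_length_axial=axial_length(tube),
        wire_lengths=[w.length for w in model.wires],
        braid_angle_measured=measure_braid_angle(model, cl),
        metal_coverage=metal_coverage(model, tube, raster_cells=raster_cells),
        pore_density=pore_density(model, tube),
    )
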