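"""Braid pattern mapping and wire sweeping.

Wires are helices in the deployed tube's (station, angle) parameter grid:
wire j of clockwise handedness follows ``theta(t) = theta0_j + 2*pi*turns*t``
over the arclength fraction t in [0, 1]; counter-clockwise wires use
``-turns``.  Parameter samples are mapped onto the *triangulated* deployed
surface (barycentric within each lattice cell), so wire points adhere to
the exported surface exactly.  All wires share one surface — crossings
overlay with no over/under weave.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .centerline import compute_frames, Centerline
from .deployment import SimplexTube
from .mesh_io import SurfaceMesh

__all__ = [
    "WireCurve",
    "StentModel",
    "generate_wire_paths",
    "braid_angle_design",
    "braid_angle_from_turns",
    "sweep_wires",
    "crossing_count",
    "SweepError",
]

DEFAULT_WIRE_DIAMETER = 0.06  # mm; assumption, not a published device fact
DEFAULT_BRAID_ANGLE = 60.0    # degrees from the stent axis; assumption
DEFAULT_N_SIDES = 8

#: maximum parameter-space wrap per sample (radians); keeps chordal error tiny
_MAX_WRAP_PER_SAMPLE = 0.1


class SweepError(RuntimeError):
    pass


@dataclasses.dataclass
class WireCurve:
    wire_index: int
    handedness: str                  # "cw" | "ccw"
    points: np.ndarray               # (M, 3)
    wire_diameter: float = 0.0
    theta0: float = 0.0              # parameter-space start angle
    signed_turns: float = 0.0        # +turns for cw, -turns for ccw
    param_t: np.ndarray | None = None      # (M,) arclength fraction
    param_theta: np.ndarray | None = None  # (M,) unwrapped angle
    outward: np.ndarray | None = None      # (M, 3) radial unit vectors

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclasses.dataclass
class StentModel:
    wires: list[WireCurve]
    swept: SurfaceMesh
    device: dict


def braid_angle_design(free_diameter: float, length: float, target_angle: float) -> float:
    """Turns giving ``target_angle`` (degrees from axis) at the free diameter."""
    if not (0.0 < target_angle < 90.0):
        raise ValueError("target_angle must lie strictly between 0 and 90 degrees")
    if free_diameter <= 0 or length <= 0:
        raise ValueError("free_diameter and length must be positive")
    return length * math.tan(math.radians(target_angle)) / (math.pi * free_diameter)


def braid_angle_from_turns(free_diameter: float, length: float, turns: float) -> float:
    """Inverse of :func:`braid_angle_design` (degrees)."""
    return math.degrees(math.atan2(math.pi * free_diameter * turns, length))


def _surface_point(tube: SimplexTube, verts: np.ndarray, s_float: float, theta: float) -> np.ndarray:
    """Map a parameter point onto the deployed-surface triangulation."""
    S, R = tube.stations, tube.rings
    dtheta = 2 * math.pi / R
    s0 = min(int(math.floor(s_float)), S - 2)
    u = s_float - s0
    th = theta % (2 * math.pi)
    j0 = min(int(math.floor(th / dtheta)), R - 1)
    v = th / dtheta - j0
    a = verts[s0, j0]
    b = verts[s0, (j0 + 1) % R]
    c = verts[s0 + 1, (j0 + 1) % R]
    d = verts[s0 + 1, j0]
    # cell split matches deployed_surface: triangles (a,b,c) and (a,c,d)
    if v >= u:
        return a * (1.0 - v) + b * (v - u) + c * u
    return a * (1.0 - u) + d * (u - v) + c * v


def generate_wire_paths(
    tube: SimplexTube, n_wires: int = 16, turns: float | None = None, phase: float = 0.0
) -> list[WireCurve]:
    """Lay ``n_wires`` helical wires (half cw, half ccw) on the deployed tube.

    ``turns`` defaults to the 60-degree braid-angle design.  ``phase`` is a
    start-angle offset in degrees.  Wires are sampled at every station and
    densified so the per-sample angular wrap stays below 0.1 rad.
    """
    if n_wires < 2 or n_wires % 2 != 0:
        raise ValueError("n_wires must be even and >= 2")
    if not tube.expanded:
        raise ValueError("tube must be expanded before pattern mapping")
    if turns is None:
        turns = braid_angle_design(
            2 * tube.cap_radius, tube.config.stent_length, DEFAULT_BRAID_ANGLE
        )
    if turns <= 0:
        raise ValueError("turns must be positive")

    S = tube.stations
    verts = tube.vertices()
    dirs = tube.radial_directions()
    n_sub = max(1, int(math.ceil(2 * math.pi * turns / ((S - 1) * _MAX_WRAP_PER_SAMPLE))))
    t = np.linspace(0.0, 1.0, (S - 1) * n_sub + 1)
    s_float = t * (S - 1)

    per_hand = n_wires // 2
    wires: list[WireCurve] = []
    for idx in range(n_wires):
        cw = idx < per_hand
        k = idx if cw else idx - per_hand
        theta0 = math.radians(phase) + 2 * math.pi * k / per_hand
        if not cw:
            # interleave the two carrier families by half a spacing so no
            # two wires share a start point (coincident cap vertices would
            # weld distinct wires together in a merged STL)
            theta0 += math.pi / per_hand
        signed = turns if cw else -turns
        theta = theta0 + 2 * math.pi * signed * t
        pts = np.array(
            [_surface_point(tube, verts, s, th) for s, th in zip(s_float, theta)]
        )
        # outward radial direction, interpolated per sample for later offsetting
        out = np.empty_like(pts)
        for i, (s, th) in enumerate(zip(s_float, theta)):
            s0 = min(int(math.floor(s)), S - 2)
            u = s - s0
            n_vec = (1 - u) * tube.frame_normal[s0] + u * tube.frame_normal[s0 + 1]
            b_vec = (1 - u) * tube.frame_binormal[s0] + u * tube.frame_binormal[s0 + 1]
            v = math.cos(th) * n_vec + math.sin(th) * b_vec
            out[i] = v / np.linalg.norm(v)
        wires.append(
            WireCurve(
                wire_index=idx,
                handedness="cw" if cw else "ccw",
                points=pts,
                theta0=theta0,
                signed_turns=signed,
                param_t=t.copy(),
                param_theta=theta,
                outward=out,
            )
        )
    _ = dirs  # lattice directions available for callers via tube
    return wires


def crossing_count(w1: WireCurve, w2: WireCurve) -> int:
    """Crossings of two wires in the unrolled parameter plane (analytic)."""
    if w1.signed_turns == w2.signed_turns:
        return 0
    dk = (w1.signed_turns - w2.signed_turns) * 2 * math.pi  # relative winding
    d0 = w2.theta0 - w1.theta0
    # theta1(t) == theta2(t) (mod 2*pi)  <=>  2*pi*m = dk*t - d0, t in [0, 1)
    lo, hi = sorted((-d0 / (2 * math.pi), (dk - d0) / (2 * math.pi)))
    count = math.ceil(hi - 1e-9) - math.ceil(lo - 1e-9)
    return max(0, int(count))


def _polygon_radius(wire_diameter: float, n_sides: int) -> float:
    """Circumradius of the area-matched regular polygon cross-section.

    An inscribed polygon at n_sides=8 would understate swept volume by ~10%;
    matching the polygon area to the circle keeps tube volume faithful.
    """
    circle = math.pi * (wire_diameter / 2.0) ** 2
    poly_unit = 0.5 * n_sides * math.sin(2 * math.pi / n_sides)
    return math.sqrt(circle / poly_unit)


def _sweep_one(points: np.ndarray, radius: float, n_sides: int, wire_index: int) -> SurfaceMesh:
    seg = np.diff(points, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    if np.any(seglen < 1e-12):
        raise SweepError(f"wire {wire_index}: coincident samples")
    unit = seg / seglen[:, None]
    cosang = np.einsum("ij,ij->i", unit[:-1], unit[1:])
    if np.any(cosang < math.cos(math.radians(60.0))):
        v = int(np.argmax(cosang < math.cos(math.radians(60.0)))) + 1
        raise SweepError(f"wire {wire_index}: kink exceeding 60 degrees at vertex {v}")

    cl = compute_frames(Centerline(points=points, arclength=np.concatenate([[0.0], np.cumsum(seglen)])))
    phi = 2 * math.pi * np.arange(n_sides) / n_sides
    rings = (
        points[:, None, :]
        + radius * np.cos(phi)[None, :, None] * cl.normal[:, None, :]
        + radius * np.sin(phi)[None, :, None] * cl.binormal[:, None, :]
    )
    M = len(points)
    verts = np.concatenate([rings.reshape(-1, 3), points[0][None], points[-1][None]])
    i0, i1 = M * n_sides, M * n_sides + 1
    faces = []
    for i in range(M - 1):
        for j in range(n_sides):
            a = i * n_sides + j
            b = i * n_sides + (j + 1) % n_sides
            c = (i + 1) * n_sides + (j + 1) % n_sides
            d = (i + 1) * n_sides + j
            faces.append((a, b, c))
            faces.append((a, c, d))
    for j in range(n_sides):
        faces.append((i0, (j + 1) % n_sides, j))
    base = (M - 1) * n_sides
    for j in range(n_sides):
        faces.append((i1, base + j, base + (j + 1) % n_sides))
    mesh = SurfaceMesh(verts, np.asarray(faces), provenance=f"wire:{wire_index}")
    if mesh.signed_volume() < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()
    return mesh


def sweep_wires(
    wires: list[WireCurve],
    wire_diameter: float = DEFAULT_WIRE_DIAMETER,
    n_sides: int = DEFAULT_N_SIDES,
    device_meta: dict | None = None,
) -> StentModel:
    """Sweep each wire into a capped watertight tube and merge (no Booleans).

    Wire centerlines are first offset radially inward by half the wire
    diameter so the swept solids stay tangent to the wall from inside.
    """
    if n_sides < 6:
        raise ValueError("n_sides must be at least 6")
    if wire_diameter <= 0:
        raise ValueError("wire_diameter must be positive")
    radius = _polygon_radius(wire_diameter, n_sides)
    all_v: list[np.ndarray] = []
    all_f: list[np.ndarray] = []
    offset_wires: list[WireCurve] = []
    nv = 0
    for w in wires:
        pts = w.points
        if w.outward is not None:
            pts = pts - (wire_diameter / 2.0) * w.outward
        mesh = _sweep_one(pts, radius, n_sides, w.wire_index)
        all_v.append(mesh.vertices)
        all_f.append(mesh.faces + nv)
        nv += mesh.n_vertices
        offset_wires.append(dataclasses.replace(w, wire_diameter=wire_diameter))
    merged = SurfaceMesh(
        np.concatenate(all_v), np.concatenate(all_f), provenance="stent:merged"
    )
    meta = {
        "n_wires": len(wires),
        "wire_diameter": wire_diameter,
        "n_sides": n_sides,
    }
    if wires:
        meta["turns"] = abs(wires[0].signed_turns)
    if device_meta:
        meta.update(device_meta)
    return StentModel(wires=offset_wires, swept=merged, device=meta)
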