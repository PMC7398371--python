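"""Parent-vessel centerline: extraction, resampling and moving frames.

Extraction is greedy maximal-inscribed-sphere marching: from a seed the
walker repeatedly steps to the point, inside a forward cone, whose
inscribed-sphere radius (distance to the lumen wall) is largest, while
strictly approaching the target seed.  A Laplacian smoothing pass cleans
the discrete dither.  Frames are rotation-minimizing (double reflection).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._geom import TriMeshQuery

__all__ = [
    "Centerline",
    "extract_centerline",
    "resample_centerline",
    "compute_frames",
    "CenterlineError",
]


class CenterlineError(RuntimeError):
    """Extraction failed (disconnected lumen, walker stuck, bad seeds)."""


@dataclasses.dataclass
class Centerline:
    """Ordered 3D polyline with arclength, RMF frames and local radius."""

    points: np.ndarray
    arclength: np.ndarray
    tangent: np.ndarray | None = None
    normal: np.ndarray | None = None
    binormal: np.ndarray | None = None
    radius: np.ndarray | None = None
    radius_source: str = ""

    @classmethod
    def from_points(cls, points, radius=None, arclength=None) -> "Centerline":
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        if len(points) < 2:
            raise ValueError("a centerline needs at least 2 points")
        if arclength is None:
            seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
            if np.any(seg == 0):
                raise ValueError("coincident consecutive points")
            arclength = np.concatenate([[0.0], np.cumsum(seg)])
        arclength = np.asarray(arclength, dtype=np.float64)
        if radius is not None:
            radius = np.asarray(radius, dtype=np.float64)
        cl = cls(points=points, arclength=arclength, radius=radius)
        return compute_frames(cl)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def point_at(self, s: float) -> np.ndarray:
        """Linear interpolation of position at arclength ``s``."""
        return np.array(
            [np.interp(s, self.arclength, self.points[:, i]) for i in range(3)]
        )

    def frame_at(self, s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Interpolated (tangent, normal, binormal), re-orthonormalized."""
        t = np.array([np.interp(s, self.arclength, self.tangent[:, i]) for i in range(3)])
        n = np.array([np.interp(s, self.arclength, self.normal[:, i]) for i in range(3)])
        t /= np.linalg.norm(t)
        n -= t * np.dot(t, n)
        n /= np.linalg.norm(n)
        return t, n, np.cross(t, n)


def compute_frames(cl: Centerline) -> Centerline:
    """Attach rotation-minimizing frames (double-reflection method)."""
    p = cl.points
    if len(p) < 2:
        raise ValueError("need at least 2 points")
    seg = np.diff(p, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    if np.any(seglen < 1e-15):
        raise ValueError("coincident consecutive points")

    tangent = np.empty_like(p)
    tangent[0] = seg[0] / seglen[0]
    tangent[-1] = seg[-1] / seglen[-1]
    if len(p) > 2:
        mid = seg[:-1] / seglen[:-1, None] + seg[1:] / seglen[1:, None]
        norms = np.linalg.norm(mid, axis=1)
        norms[norms < 1e-15] = 1.0
        tangent[1:-1] = mid / norms[:, None]

    # initial normal: any unit vector orthogonal to t0
    t0 = tangent[0]
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, t0)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n0 = ref - t0 * np.dot(ref, t0)
    n0 /= np.linalg.norm(n0)

    normal = np.empty_like(p)
    normal[0] = n0
    for i in range(len(p) - 1):
        # double reflection (Wang et al. 2008)
        v1 = p[i + 1] - p[i]
        c1 = np.dot(v1, v1)
        rl = normal[i] - (2.0 / c1) * np.dot(v1, normal[i]) * v1
        tl = tangent[i] - (2.0 / c1) * np.dot(v1, tangent[i]) * v1
        v2 = tangent[i + 1] - tl
        c2 = np.dot(v2, v2)
        n_next = rl if c2 < 1e-15 else rl - (2.0 / c2) * np.dot(v2, rl) * v2
        n_next -= tangent[i + 1] * np.dot(tangent[i + 1], n_next)
        normal[i + 1] = n_next / np.linalg.norm(n_next)

    cl.tangent = tangent
    cl.normal = normal
    cl.binormal = np.cross(tangent, normal)
    return cl


def resample_centerline(cl: Centerline, spacing: float) -> Centerline:
    """Resample to uniform arclength spacing; endpoints preserved.

    The actual spacing is total/(n-1) with n = round(total/spacing)+1, so
    resampling an already-uniform polyline is an exact no-op.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    total = cl.length
    if spacing >= total:
        raise ValueError(f"spacing {spacing} >= total arclength {total}")
    n = int(round(total / spacing)) + 1
    s_new = np.linspace(0.0, total, n)
    pts = np.column_stack(
        [np.interp(s_new, cl.arclength, cl.points[:, i]) for i in range(3)]
    )
    radius = (
        np.interp(s_new, cl.arclength, cl.radius) if cl.radius is not None else None
    )
    # the output inherits the input's parameterization (s_new), which makes
    # resampling at the same spacing exactly idempotent
    out = Centerline.from_points(pts, radius=radius, arclength=s_new)
    out.radius_source = cl.radius_source
    return out


def _cone_directions(heading: np.ndarray, half_angle_deg: float = 60.0) -> np.ndarray:
    """Deterministic direction fan inside a cone around ``heading``."""
    heading = heading / np.linalg.norm(heading)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, heading)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - heading * np.dot(ref, heading)
    u /= np.linalg.norm(u)
    v = np.cross(heading, u)
    dirs = [heading]
    for polar in (10.0, 20.0, 30.0, 45.0, float(half_angle_deg)):
        pr = np.radians(polar)
        for az in np.arange(0.0, 360.0, 45.0):
            ar = np.radians(az)
            d = (
                np.cos(pr) * heading
                + np.sin(pr) * (np.cos(ar) * u + np.sin(ar) * v)
            )
            dirs.append(d)
    return np.asarray(dirs)


def _recenter(pts: np.ndarray, query: TriMeshQuery) -> np.ndarray:
    """Pattern-search each interior point toward the local medial axis.

    Moves points only within the plane perpendicular to the local tangent,
    maximizing the inscribed-sphere radius.  Undoes both the inward shrink
    of Laplacian smoothing and the chord-cutting of the greedy march.
    """
    pts = pts.copy()
    n = len(pts)
    if n < 3:
        return pts
    for trial_radius in (0.3, 0.15, 0.06, 0.02):
        for _ in range(3):
            tang = np.empty_like(pts)
            tang[1:-1] = pts[2:] - pts[:-2]
            tang[0] = pts[1] - pts[0]
            tang[-1] = pts[-1] - pts[-2]
            tang /= np.linalg.norm(tang, axis=1)[:, None]
            ref = np.where(
                np.abs(tang @ np.array([1.0, 0.0, 0.0]))[:, None] > 0.9,
                np.array([0.0, 1.0, 0.0]),
                np.array([1.0, 0.0, 0.0]),
            )
            u = ref - tang * np.einsum("ij,ij->i", ref, tang)[:, None]
            u /= np.linalg.norm(u, axis=1)[:, None]
            v = np.cross(tang, u)
            best = query.distance(pts)
            moved = False
            for az in np.arange(0.0, 360.0, 45.0):
                ar = np.radians(az)
                cand = pts + trial_radius * (np.cos(ar) * u + np.sin(ar) * v)
                d = query.distance(cand)
                better = d > best + 1e-12
                better[0] = better[-1] = False  # endpoints pinned
                if np.any(better):
                    pts[better] = cand[better]
                    best[better] = d[better]
                    moved = True
            if not moved:
                break
    return pts


def extract_centerline(mesh, seed_a, seed_b, step: float | None = None) -> Centerline:
    """March a maximal-inscribed-sphere path from ``seed_a`` to ``seed_b``.

    Parameters
    ----------
    mesh : SurfaceMesh
        Watertight lumen surface.
    seed_a, seed_b : (3,) points strictly inside the lumen.
    step : optional fixed step (mm); default is adaptive 0.5 x local radius.
    """
    query = TriMeshQuery(mesh)
    seed_a = np.asarray(seed_a, dtype=np.float64)
    seed_b = np.asarray(seed_b, dtype=np.float64)
    inside = query.contains(np.stack([seed_a, seed_b]))
    if not inside[0]:
        raise ValueError("seed_a lies outside the lumen")
    if not inside[1]:
        raise ValueError("seed_b lies outside the lumen")

    points = [seed_a.copy()]
    radii = [float(query.distance(seed_a[None])[0])]
    heading = seed_b - seed_a
    heading /= np.linalg.norm(heading)

    span = np.linalg.norm(seed_b - seed_a)
    max_steps = int(20 * span / max(0.25 * radii[0], 1e-3)) + 200
    for _ in range(max_steps):
        current = points[-1]
        r_local = radii[-1]
        h = step if step is not None else 0.5 * r_local
        h = max(h, 1e-3)
        dist_to_target = np.linalg.norm(seed_b - current)
        if dist_to_target <= 1.25 * h:
            break
        dirs = _cone_directions(heading)
        cand = current + h * dirs
        # progress guard: each step must strictly approach the target
        keep = np.linalg.norm(cand - seed_b, axis=1) < dist_to_target - 0.05 * h
        cand = cand[keep]
        dirs = dirs[keep]
        if len(cand) == 0:
            raise CenterlineError("walker cannot progress toward seed_b")
        rad = query.distance(cand)
        order = np.argsort(-rad)
        chosen = None
        for j in order[:4]:
            if query.contains(cand[j][None])[0]:
                chosen = j
                break
        if chosen is None:
            raise CenterlineError("no inside candidate in the forward cone")
        new_heading = dirs[chosen]
        heading = 0.6 * heading + 0.4 * new_heading
        heading /= np.linalg.norm(heading)
        points.append(cand[chosen])
        radii.append(float(rad[chosen]))
    else:
        raise CenterlineError("maximum step count exceeded (disconnected lumen?)")

    points.append(seed_b.copy())
    pts = np.asarray(points)

    # Laplacian smoothing, endpoints pinned
    w = 0.5
    for _ in range(10):
        if len(pts) < 3:
            break
        interior = pts[1:-1] + w * (0.5 * (pts[:-2] + pts[2:]) - pts[1:-1])
        pts = np.vstack([pts[0], interior, pts[-1]])

    # drop accidental duplicates after smoothing
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-9])
    pts = pts[keep]

    pts = _recenter(pts, query)

    radius = query.distance(pts)
    cl = Centerline.from_points(pts, radius=radius)
    cl.radius_source = "inscribed-sphere"
    return cl
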