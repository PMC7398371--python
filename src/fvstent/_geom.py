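"""Ray/distance queries against triangle meshes.

Small internal engine used by centerline extraction, deployment contact
queries and mesh-based metrics.  Acceleration is a cKDTree over triangle
centroids; queries fall back to a full scan whenever the local candidate
set cannot guarantee correctness, so results are exact.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

_EPS = 1e-12

# slightly irrational direction so parity rays almost never graze an edge
_PARITY_DIR = np.array([0.5735764363510262, 0.5876902922677589, 0.5707372016677029])
_PARITY_DIR /= np.linalg.norm(_PARITY_DIR)


def _moller_trumbore(origin, direction, v0, e1, e2):
    """Ray-hit parameters t (>=0) against a triangle batch; NaN where missed."""
    pvec = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > _EPS
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), np.nan)
    tvec = origin - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv
    qvec = np.cross(tvec, e1)
    v = np.dot(qvec, direction) * inv
    t = np.einsum("ij,ij->i", e2, qvec) * inv
    hit = ok & (u >= -1e-10) & (v >= -1e-10) & (u + v <= 1.0 + 1e-10) & (t > 1e-9)
    return np.where(hit, t, np.nan)


def closest_point_on_triangles(p, v0, e1, e2):
    """Vectorized closest point on each triangle (Ericson, RTCD §5.1.5)."""
    a = np.einsum("ij,ij->i", e1, e1)
    b = np.einsum("ij,ij->i", e1, e2)
    c = np.einsum("ij,ij->i", e2, e2)
    dp = p - v0
    d = np.einsum("ij,ij->i", e1, dp)
    e = np.einsum("ij,ij->i", e2, dp)
    det = a * c - b * b
    det = np.where(det < _EPS, _EPS, det)
    s = (c * d - b * e) / det
    t = (a * e - b * d) / det
    # clamp to triangle: interior first, then edges
    s = np.clip(s, 0.0, 1.0)
    t = np.clip(t, 0.0, 1.0)
    over = s + t > 1.0
    if np.any(over):
        # project onto hypotenuse edge s+t=1
        e12 = e2[over] - e1[over]
        pp = p - (v0[over] + e1[over])
        tt = np.einsum("ij,ij->i", e12, pp) / np.maximum(
            np.einsum("ij,ij->i", e12, e12), _EPS
        )
        tt = np.clip(tt, 0.0, 1.0)
        s[over] = 1.0 - tt
        t[over] = tt
    # re-clamp the axis edges with proper 1D projections
    s0 = s <= 0.0
    t0 = t <= 0.0
    if np.any(t0):
        ss = np.clip(d[t0] / np.maximum(a[t0], _EPS), 0.0, 1.0)
        s[t0] = ss
        t[t0] = 0.0
    if np.any(s0):
        tt = np.clip(e[s0] / np.maximum(c[s0], _EPS), 0.0, 1.0)
        s[s0] = 0.0
        t[s0] = tt
    return v0 + s[:, None] * e1 + t[:, None] * e2


def _moller_trumbore_batch(origins, directions, v0, e1, e2):
    """(n_rays, n_tris) hit parameters; NaN where missed."""
    pvec = np.cross(directions[:, None, :], e2[None, :, :])
    det = np.einsum("nmj,mj->nm", pvec, e1)
    ok = np.abs(det) > _EPS
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), np.nan)
    tvec = origins[:, None, :] - v0[None, :, :]
    u = np.einsum("nmj,nmj->nm", tvec, pvec) * inv
    qvec = np.cross(tvec, e1[None, :, :])
    v = np.einsum("nmj,nj->nm", qvec, directions) * inv
    t = np.einsum("nmj,mj->nm", qvec, e2) * inv
    hit = ok & (u >= -1e-10) & (v >= -1e-10) & (u + v <= 1.0 + 1e-10) & (t > 1e-9)
    return np.where(hit, t, np.nan)


class TriMeshQuery:
    """Immutable query accelerator for a triangle mesh."""

    def __init__(self, mesh):
        tris = mesh.triangles()
        self.v0 = np.ascontiguousarray(tris[:, 0])
        self.e1 = np.ascontiguousarray(tris[:, 1] - tris[:, 0])
        self.e2 = np.ascontiguousarray(tris[:, 2] - tris[:, 0])
        self.centroids = tris.mean(axis=1)
        self.tri_radius = np.linalg.norm(
            tris - self.centroids[:, None, :], axis=2
        ).max(axis=1)
        self.max_tri_radius = float(self.tri_radius.max()) if len(tris) else 0.0
        self.tree = cKDTree(self.centroids)
        self.n = len(tris)

    # -- ray queries --------------------------------------------------------

    def ray_hits(self, origin, direction):
        """All positive hit distances, sorted ascending (full scan)."""
        t = _moller_trumbore(
            np.asarray(origin, float), np.asarray(direction, float),
            self.v0, self.e1, self.e2,
        )
        t = t[np.isfinite(t)]
        t.sort()
        return t

    def first_hit(self, origin, direction, search_radius=None):
        """Distance to the first intersection; inf if the ray misses.

        ``search_radius`` enables a local candidate pass; the answer is
        accepted only when provably complete, else a full scan runs.
        """
        origin = np.asarray(origin, float)
        direction = np.asarray(direction, float)
        if search_radius is not None and self.n > 512:
            idx = self.tree.query_ball_point(
                origin, search_radius + self.max_tri_radius
            )
            if idx:
                idx = np.asarray(idx)
                t = _moller_trumbore(
                    origin, direction, self.v0[idx], self.e1[idx], self.e2[idx]
                )
                t = t[np.isfinite(t)]
                if len(t) and t.min() <= search_radius:
                    return float(t.min())
        t = self.ray_hits(origin, direction)
        return float(t[0]) if len(t) else float("inf")

    def first_hits(self, origins, directions, search_radius=None):
        """Vector form of :meth:`first_hit` over matched point/direction rows.

        With ``search_radius`` the KD-tree candidate lookup is batched; any
        ray whose local result is not provably complete falls back to a
        full scan.
        """
        origins = np.asarray(origins, float)
        directions = np.asarray(directions, float)
        out = np.empty(len(origins))
        if search_radius is not None and self.n > 512:
            cand_lists = self.tree.query_ball_point(
                origins, search_radius + self.max_tri_radius
            )
            for i, (o, d) in enumerate(zip(origins, directions)):
                idx = cand_lists[i]
                if idx:
                    ia = np.asarray(idx)
                    t = _moller_trumbore(o, d, self.v0[ia], self.e1[ia], self.e2[ia])
                    t = t[np.isfinite(t)]
                    if len(t) and t.min() <= search_radius:
                        out[i] = float(t.min())
                        continue
                out[i] = self.first_hit(o, d)
            return out
        for i, (o, d) in enumerate(zip(origins, directions)):
            out[i] = self.first_hit(o, d, search_radius=search_radius)
        return out

    def first_hits_clustered(self, origins, directions, cluster_center, l_max,
                             candidates=None):
        """First-hit distances for rays sharing a spatial cluster.

        All hits with t <= ``l_max`` are guaranteed found when the rays
        start within ``l_max`` of ``cluster_center``; longer hits trigger a
        per-ray full scan.  ``candidates`` may carry a precomputed index
        array for the cluster.
        """
        origins = np.asarray(origins, float)
        directions = np.asarray(directions, float)
        if candidates is None:
            spread = np.linalg.norm(origins - cluster_center, axis=1).max()
            candidates = np.asarray(
                self.tree.query_ball_point(
                    cluster_center, l_max + spread + self.max_tri_radius
                ),
                dtype=int,
            )
        out = np.full(len(origins), np.inf)
        if len(candidates):
            t = _moller_trumbore_batch(
                origins, directions,
                self.v0[candidates], self.e1[candidates], self.e2[candidates],
            )
            any_hit = np.any(np.isfinite(t), axis=1)
            t = np.where(np.isfinite(t), t, np.inf)
            out = np.where(any_hit, t.min(axis=1), np.inf)
        bad = ~(out <= l_max)
        for i in np.flatnonzero(bad):
            out[i] = self.first_hit(origins[i], directions[i])
        return out

    # -- containment --------------------------------------------------------

    def contains(self, points):
        """Ray-parity inside test for a batch of points (watertight input)."""
        points = np.atleast_2d(np.asarray(points, float))
        out = np.empty(len(points), dtype=bool)
        for i, p in enumerate(points):
            hits = self.ray_hits(p, _PARITY_DIR)
            out[i] = (len(hits) % 2) == 1
        return out

    # -- distance -----------------------------------------------------------

    def distance(self, points, k: int = 12):
        """Exact unsigned distance from each point to the surface."""
        points = np.atleast_2d(np.asarray(points, float))
        k = min(k, self.n)
        _, nearest = self.tree.query(points, k=k)
        nearest = np.atleast_2d(nearest)
        out = np.empty(len(points))
        for i, p in enumerate(points):
            idx = nearest[i]
            cp = closest_point_on_triangles(p, self.v0[idx], self.e1[idx], self.e2[idx])
            d = np.linalg.norm(cp - p, axis=1).min()
            # candidate set is complete iff no unexamined centroid can be
            # closer than d + its triangle radius
            bound = d + self.max_tri_radius
            extra = self.tree.query_ball_point(p, bound)
            extra = np.setdiff1d(np.asarray(extra, dtype=int), idx, assume_unique=False)
            if len(extra):
                cp2 = closest_point_on_triangles(
                    p, self.v0[extra], self.e1[extra], self.e2[extra]
                )
                d = min(d, np.linalg.norm(cp2 - p, axis=1).min())
            out[i] = d
        return out
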