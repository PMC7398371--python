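"""Surface-mesh and polyline I/O plus structural validation.

All geometry is in millimetres.  STL carries no unit metadata, so the mm
convention is contractual.  Coordinates are right-handed and triangle
winding is counter-clockwise seen from outside (signed volume > 0 for a
closed outward-oriented mesh).
"""

from __future__ import annotations

import dataclasses
import json
import struct
from pathlib import Path

import numpy as np

__all__ = [
    "SurfaceMesh",
    "ValidationReport",
    "MeshFormatError",
    "read_surface_mesh",
    "write_surface_mesh",
    "read_polyline",
    "write_polyline",
    "validate_mesh",
]

#: vertices closer than this (mm) are merged on read; STL stores a triangle soup
VERTEX_MERGE_TOL = 1e-6

_DEGENERATE_AREA = 1e-12  # mm^2


class MeshFormatError(ValueError):
    """Raised when a geometry file is structurally unusable."""


@dataclasses.dataclass
class SurfaceMesh:
    """Triangulated surface: ``vertices`` (n,3) float64 mm, ``faces`` (m,3) int."""

    vertices: np.ndarray
    faces: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")
        if len(self.faces) and self.faces.min() < 0:
            raise ValueError("negative face index")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """Return (m, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_normals(self) -> np.ndarray:
        t = self.triangles()
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        lens = np.linalg.norm(n, axis=1)
        lens[lens == 0] = 1.0
        return n / lens[:, None]

    def face_areas(self) -> np.ndarray:
        t = self.triangles()
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    def signed_volume(self) -> float:
        """Divergence-theorem volume; positive for outward orientation."""
        t = self.triangles()
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)


@dataclasses.dataclass
class ValidationReport:
    watertight: bool
    n_nonmanifold_edges: int
    n_degenerate_faces: int
    bbox_min: tuple[float, float, float]
    bbox_max: tuple[float, float, float]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


def _merge_duplicate_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: float = VERTEX_MERGE_TOL
) -> tuple[np.ndarray, np.ndarray]:
    """Weld vertices coincident within ``tol`` by snapping to a grid."""
    if len(vertices) == 0:
        return vertices, faces
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    return vertices[first], inverse[faces]


def validate_mesh(mesh: SurfaceMesh) -> ValidationReport:
    """Structural report: manifoldness, degeneracy, orientation, bbox.

    Pure — never mutates the mesh.  ``watertight`` means every edge is
    shared by exactly two faces with opposite direction (consistent
    orientation), no degenerate faces, and positive enclosed volume.
    """
    faces = mesh.faces
    if len(faces) == 0:
        return ValidationReport(False, 0, 0, (0.0,) * 3, (0.0,) * 3)

    areas = mesh.face_areas()
    repeated = (
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 0] == faces[:, 2])
    )
    n_degenerate = int(np.count_nonzero((areas < _DEGENERATE_AREA) | repeated))

    # undirected edge multiplicity
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    und = np.sort(e, axis=1)
    _, counts = np.unique(und, axis=0, return_counts=True)
    n_nonmanifold = int(np.count_nonzero(counts != 2))

    # orientation consistency: every directed edge appears exactly once
    _, dcounts = np.unique(e, axis=0, return_counts=True)
    oriented = bool(np.all(dcounts == 1))

    watertight = (
        n_nonmanifold == 0
        and n_degenerate == 0
        and oriented
        and mesh.signed_volume() > 0
    )
    lo, hi = mesh.bounds()
    return ValidationReport(
        watertight=watertight,
        n_nonmanifold_edges=n_nonmanifold,
        n_degenerate_faces=n_degenerate,
        bbox_min=tuple(float(x) for x in lo),
        bbox_max=tuple(float(x) for x in hi),
    )


def split_connected_components(mesh: SurfaceMesh) -> list[SurfaceMesh]:
    """Split into vertex-connected components (largest first)."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    e = np.concatenate(
        [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
    )
    n = mesh.n_vertices
    adj = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    out = []
    for c in range(n_comp):
        vmask = labels == c
        if not np.any(vmask):
            continue
        fmask = vmask[mesh.faces[:, 0]]
        remap = -np.ones(n, dtype=np.int64)
        vidx = np.flatnonzero(vmask)
        remap[vidx] = np.arange(len(vidx))
        out.append(
            SurfaceMesh(
                mesh.vertices[vidx],
                remap[mesh.faces[fmask]],
                provenance=f"{mesh.provenance}#component{c}",
            )
        )
    out.sort(key=lambda m: -m.n_faces)
    return out


# ---------------------------------------------------------------------------
# STL
# ---------------------------------------------------------------------------

def _is_binary_stl(path: Path) -> bool:
    size = path.stat().st_size
    if size < 84:
        return False
    with open(path, "rb") as fh:
        header = fh.read(80)
        (count,) = struct.unpack("<I", fh.read(4))
    if size == 84 + 50 * count:
        return True
    # ASCII files start with "solid"; some binary exporters do too, hence the
    # size check above takes precedence.
    return not header.lstrip().lower().startswith(b"solid")


def read_surface_mesh(path, dialect: str = "auto") -> SurfaceMesh:
    """Read an STL file (ASCII or binary) into an indexed :class:`SurfaceMesh`.

    Duplicate vertices within 1e-6 mm are merged; the face count is
    preserved from the file.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"cannot read mesh file: {path}")
    if dialect not in ("auto", "stl_ascii", "stl_binary"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "auto":
        dialect = "stl_binary" if _is_binary_stl(path) else "stl_ascii"

    if dialect == "stl_binary":
        with open(path, "rb") as fh:
            fh.read(80)
            raw = fh.read(4)
            if len(raw) < 4:
                raise MeshFormatError(f"truncated binary STL: {path}")
            (count,) = struct.unpack("<I", raw)
            rec = np.dtype(
                [("normal", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]
            )
            data = np.fromfile(fh, dtype=rec, count=count)
        if len(data) != count:
            raise MeshFormatError(f"binary STL facet count mismatch: {path}")
        soup = data["v"].astype(np.float64).reshape(-1, 3)
    else:
        soup_list: list[list[float]] = []
        with open(path, "r", errors="replace") as fh:
            for line in fh:
                parts = line.split()
                if parts[:1] == ["vertex"]:
                    if len(parts) != 4:
                        raise MeshFormatError(f"malformed vertex line in {path}")
                    try:
                        soup_list.append([float(parts[1]), float(parts[2]), float(parts[3])])
                    except ValueError as exc:
                        raise MeshFormatError(f"non-numeric vertex in {path}") from exc
        soup = np.asarray(soup_list, dtype=np.float64).reshape(-1, 3)
        if len(soup) % 3 != 0:
            raise MeshFormatError(f"ASCII STL vertex count not divisible by 3: {path}")

    if len(soup) == 0:
        raise MeshFormatError(f"STL file has no facets: {path}")
    faces = np.arange(len(soup), dtype=np.int64).reshape(-1, 3)
    vertices, faces = _merge_duplicate_vertices(soup, faces)
    return SurfaceMesh(vertices, faces, provenance=f"{dialect}:{path.name}")


def write_surface_mesh(mesh: SurfaceMesh, path, dialect: str = "stl_binary") -> None:
    """Write ``mesh`` as STL; binary uses the standard 80-byte-header layout."""
    if mesh.n_faces == 0:
        raise MeshFormatError("refusing to write an empty mesh")
    if dialect not in ("stl_ascii", "stl_binary"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    tris = mesh.triangles()
    normals = mesh.face_normals()
    if dialect == "stl_binary":
        rec = np.dtype([("normal", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")])
        data = np.zeros(len(tris), dtype=rec)
        data["normal"] = normals.astype(np.float32)
        data["v"] = tris.astype(np.float32)
        with open(path, "wb") as fh:
            fh.write(b"fvstent".ljust(80, b"\0"))
            fh.write(struct.pack("<I", len(tris)))
            data.tofile(fh)
    else:
        with open(path, "w") as fh:
            fh.write("solid fvstent\n")
            for n, t in zip(normals, tris):
                fh.write(f"  facet normal {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}\n")
                fh.write("    outer loop\n")
                for v in t:
                    fh.write(f"      vertex {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write("endsolid fvstent\n")


# ---------------------------------------------------------------------------
# Centerline CSV
# ---------------------------------------------------------------------------

def read_polyline(path):
    """Read a centerline CSV (``x,y,z[,radius]`` header, mm) into a Centerline."""
    from .centerline import Centerline  # local import: avoid cycle

    path = Path(path)
    if not path.is_file():
        raise IOError(f"cannot read polyline file: {path}")
    with open(path) as fh:
        header = fh.readline().strip().lower().split(",")
        if header[:3] != ["x", "y", "z"]:
            raise MeshFormatError(f"polyline header must start x,y,z: {path}")
        has_radius = len(header) >= 4 and header[3] == "radius"
        rows = []
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise MeshFormatError(f"non-numeric cell at {path}:{ln}") from exc
    if len(rows) < 2:
        raise MeshFormatError(f"polyline needs at least 2 points: {path}")
    arr = np.asarray(rows, dtype=np.float64)
    points = arr[:, :3]
    radius = arr[:, 3] if has_radius and arr.shape[1] >= 4 else None
    cl = Centerline.from_points(points, radius=radius)
    cl.radius_source = "from file" if has_radius else ""
    return cl


def write_polyline(cl, path) -> None:
    """Write a centerline as CSV with full double precision (%.17g)."""
    path = Path(path)
    has_radius = cl.radius is not None
    with open(path, "w") as fh:
        fh.write("x,y,z,radius\n" if has_radius else "x,y,z\n")
        for i, p in enumerate(cl.points):
            row = f"{p[0]:.17g},{p[1]:.17g},{p[2]:.17g}"
            if has_radius:
                row += f",{cl.radius[i]:.17g}"
            fh.write(row + "\n")
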