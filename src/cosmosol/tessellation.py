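"""Spherical triangular meshes for cavity discretization (GEPOL-style).

Each atomic (or auxiliary) sphere is covered by a pentakisdodecahedron
— 60 spherical triangles — optionally refined by midpoint 4-splits to 240
or 960 triangles.  Triangle "centers" are radially projected centroids and
areas are exact spherical-triangle areas (l'Huilier), so the tesserae of a
full sphere partition 4πR² to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TriangleMesh",
    "TessLevel",
    "Tessera",
    "LEVELS",
    "get_level",
    "pentakisdodecahedron",
    "subdivide",
    "tessellate_sphere",
    "spherical_triangle_areas",
]


@dataclass(frozen=True)
class TessLevel:
    """Tessellation refinement level: 60 × 4**subdivisions faces per sphere."""

    label: str
    subdivisions: int

    @property
    def faces_per_sphere(self) -> int:
        return 60 * 4**self.subdivisions


LEVELS: dict[str, TessLevel] = {
    "coarse": TessLevel("coarse", 0),
    "fine": TessLevel("fine", 1),
    "xfine": TessLevel("xfine", 2),
}


def get_level(level: "str | TessLevel") -> TessLevel:
    if isinstance(level, TessLevel):
        return level
    try:
        return LEVELS[level]
    except KeyError:
        raise ValueError(
            f"unknown tessellation level {level!r}; choose from {sorted(LEVELS)}"
        ) from None


@dataclass
class TriangleMesh:
    """Triangulation of the unit sphere.

    vertices : (nv, 3) unit vectors
    faces    : (nf, 3) vertex indices, outward (counter-clockwise seen from
               outside) orientation
    """

    vertices: np.ndarray
    faces: np.ndarray

    @property
    def face_centers(self) -> np.ndarray:
        """Radially projected face centroids (unit vectors)."""
        c = self.vertices[self.faces].mean(axis=1)
        return c / np.linalg.norm(c, axis=1, keepdims=True)

    @property
    def face_areas(self) -> np.ndarray:
        """Exact spherical areas (steradians)."""
        v = self.vertices[self.faces]
        return spherical_triangle_areas(v[:, 0], v[:, 1], v[:, 2])

    def edges(self) -> set[tuple[int, int]]:
        e: set[tuple[int, int]] = set()
        for i, j, k in self.faces:
            for a, b in ((i, j), (j, k), (k, i)):
                e.add((min(a, b), max(a, b)))
        return e


def _arc(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Great-circle arc length between unit vectors (rows)."""
    cross = np.linalg.norm(np.cross(u, v), axis=-1)
    dot = np.einsum("...i,...i->...", u, v)
    return np.arctan2(cross, dot)


def spherical_triangle_areas(
    a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> np.ndarray:
    """Spherical excess of triangles with unit-vector vertices (l'Huilier)."""
    la, lb, lc = _arc(b, c), _arc(a, c), _arc(a, b)
    s = 0.5 * (la + lb + lc)
    t = (
        np.tan(0.5 * s)
        * np.tan(0.5 * (s - la))
        * np.tan(0.5 * (s - lb))
        * np.tan(0.5 * (s - lc))
    )
    return 4.0 * np.arctan(np.sqrt(np.maximum(t, 0.0)))


def _dodecahedron_vertices() -> np.ndarray:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    inv = 1.0 / phi
    pts = []
    for sx in (-1.0, 1.0):
        for sy in (-1.0, 1.0):
            for sz in (-1.0, 1.0):
                pts.append((sx, sy, sz))
    for s1 in (-1.0, 1.0):
        for s2 in (-1.0, 1.0):
            pts.append((0.0, s1 * inv, s2 * phi))
            pts.append((s1 * inv, s2 * phi, 0.0))
            pts.append((s1 * phi, 0.0, s2 * inv))
    v = np.asarray(pts)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _dodecahedron_faces(dod: np.ndarray) -> np.ndarray:
    """Unit directions of the 12 pentagonal face centers.

    Found by grouping the coplanar triangles of the convex hull, which
    avoids committing to a particular dual-icosahedron orientation.
    """
    from scipy.spatial import ConvexHull

    hull = ConvexHull(dod)
    groups: dict[tuple[int, ...], set[int]] = {}
    for simplex, eq in zip(hull.simplices, hull.equations):
        key = tuple(np.round(eq[:3] / np.linalg.norm(eq[:3]), 6).astype(float))
        key = tuple(int(round(v * 1e6)) for v in key)
        groups.setdefault(key, set()).update(int(i) for i in simplex)
    centers = []
    for members in groups.values():
        c = dod[sorted(members)].mean(axis=0)
        centers.append(c / np.linalg.norm(c))
    return np.asarray(centers)


def pentakisdodecahedron() -> TriangleMesh:
    """The 60-face seed mesh.

    Built from the regular dodecahedron by apexing each pentagonal face at
    its radially projected center, giving 32 vertices, 90 edges, 60 faces.
    """
    dod = _dodecahedron_vertices()
    apexes = _dodecahedron_faces(dod)
    vertices = np.vstack([dod, apexes])
    faces = []
    for ai, apex in enumerate(apexes):
        ring = np.argsort(dod @ apex)[-5:]  # the 5 pentagon corners
        # order the corners by azimuth around the apex direction
        ref = dod[ring[0]] - (dod[ring[0]] @ apex) * apex
        ref /= np.linalg.norm(ref)
        ref2 = np.cross(apex, ref)
        ang = np.arctan2(dod[ring] @ ref2, dod[ring] @ ref)
        ring = ring[np.argsort(ang)]
        for k in range(5):
            i, j = ring[k], ring[(k + 1) % 5]
            tri = [20 + ai, int(i), int(j)]
            a, b, c = vertices[tri]
            if np.dot(np.cross(b - a, c - a), a) < 0:  # enforce outward
                tri = [tri[0], tri[2], tri[1]]
            faces.append(tri)
    return TriangleMesh(vertices=vertices, faces=np.asarray(faces, dtype=np.intp))


def subdivide(mesh: TriangleMesh, k: int) -> TriangleMesh:
    """Refine by `k` midpoint 4-splits with radial projection of midpoints."""
    if k < 0:
        raise ValueError("subdivision count must be >= 0")
    if k == 0:
        return mesh
    verts = [v for v in mesh.vertices]
    midpoint: dict[tuple[int, int], int] = {}

    def mid(i: int, j: int) -> int:
        key = (min(i, j), max(i, j))
        idx = midpoint.get(key)
        if idx is None:
            m = verts[i] + verts[j]
            m = m / np.linalg.norm(m)
            idx = len(verts)
            verts.append(m)
            midpoint[key] = idx
        return idx

    faces = []
    for i, j, l in mesh.faces:
        a, b, c = mid(i, j), mid(j, l), mid(l, i)
        faces.extend([(i, a, c), (j, b, a), (l, c, b), (a, b, c)])
    out = TriangleMesh(
        vertices=np.asarray(verts), faces=np.asarray(faces, dtype=np.intp)
    )
    return subdivide(out, k - 1)


_MESH_CACHE: dict[int, TriangleMesh] = {}


def unit_mesh(level: "str | TessLevel") -> TriangleMesh:
    """Cached unit-sphere mesh at the requested level."""
    lvl = get_level(level)
    if lvl.subdivisions not in _MESH_CACHE:
        _MESH_CACHE[lvl.subdivisions] = subdivide(
            pentakisdodecahedron(), lvl.subdivisions
        )
    return _MESH_CACHE[lvl.subdivisions]


@dataclass
class Tessera:
    """One spherical-triangle surface patch of a sphere.

    center is the radially projected centroid (on the sphere surface, Å),
    area the exact spherical-triangle area (Å²), normal the outward unit
    vector; vertices (3, 3) are kept for boundary clipping.
    """

    center: np.ndarray
    area: float
    normal: np.ndarray
    vertices: np.ndarray
    sphere_id: int = -1


def tessellate_sphere(
    center: np.ndarray,
    radius: float,
    level: "str | TessLevel",
    sphere_id: int = -1,
) -> list[Tessera]:
    """Place the unit mesh on a sphere of given center/radius (Å)."""
    if radius <= 0:
        raise ValueError(f"sphere radius must be positive, got {radius}")
    center = np.asarray(center, dtype=float)
    mesh = unit_mesh(level)
    normals = mesh.face_centers
    centers = center + radius * normals
    areas = mesh.face_areas * radius**2
    tri = center + radius * mesh.vertices[mesh.faces]
    return [
        Tessera(
            center=centers[i],
            area=float(areas[i]),
            normal=normals[i],
            vertices=tri[i],
            sphere_id=sphere_id,
        )
        for i in range(len(mesh.faces))
    ]
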