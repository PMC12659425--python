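"""Molecular cavity construction: vdW and approximate SES (GEPOL-style).

The van der Waals cavity is the union of atom-centered spheres; each sphere
is tessellated and tesserae buried inside other spheres are removed.
Tesserae straddling a sphere-sphere boundary are refined by one secondary
4-split, and exposed secondary tesserae are kept as independent segments
(no regrouping back into parents).

The solvent-excluding surface is approximated by augmenting the atomic
spheres with auxiliary spheres that fill regions inaccessible to a probe
of radius `rsolv` before the same clipping is applied; the probe controls
accessibility only and adds no thickness.

Finally, segments whose centers fall closer than a minimum distance d_min
are merged (transitive closure) to protect the point-charge Coulomb matrix
from near-singularities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .tessellation import (
    TessLevel,
    Tessera,
    get_level,
    spherical_triangle_areas,
    tessellate_sphere,
    unit_mesh,
)

__all__ = [
    "Sphere",
    "Segment",
    "Cavity",
    "CavityParams",
    "build_vdw_cavity",
    "gepol_add_spheres",
    "build_ses_cavity",
    "build_cavity",
    "compute_area_volume",
    "compute_d_min",
    "merge_segments",
]

AUXILIARY = "auxiliary"


@dataclass
class Sphere:
    center: np.ndarray  # Å
    radius: float  # Å
    origin: "int | str" = AUXILIARY  # atom index, or the auxiliary marker

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError(f"sphere radius must be positive, got {self.radius}")


@dataclass
class Segment:
    """A surface patch carrying a uniform screening charge density."""

    center: np.ndarray  # Å
    area: float  # Å²
    normal: np.ndarray  # outward unit vector
    sphere_id: int
    merged_count: int = 1


@dataclass
class Cavity:
    spheres: list[Sphere]
    segments: list[Segment]
    area: float  # Å²
    volume: float  # Å³

    @property
    def centers(self) -> np.ndarray:
        return np.array([s.center for s in self.segments])

    @property
    def areas(self) -> np.ndarray:
        return np.array([s.area for s in self.segments])

    @property
    def normals(self) -> np.ndarray:
        return np.array([s.normal for s in self.segments])


@dataclass
class CavityParams:
    cavity_type: str = "vdw"  # "vdw" | "ses"
    level: "str | TessLevel" = "fine"
    rsolv: float = 1.3  # probe radius, Å
    mfactor: float = 1.0  # scales d_min; 0 disables merging
    ofac: float = 0.8  # overlap factor above which no auxiliary sphere is added
    rmin: float = 0.5  # minimum auxiliary sphere radius, Å

    def __post_init__(self) -> None:
        if self.cavity_type not in ("vdw", "ses"):
            raise ValueError(f"cavity_type must be 'vdw' or 'ses', got {self.cavity_type!r}")
        if self.rsolv < 0:
            raise ValueError("rsolv must be >= 0")
        if self.mfactor < 0:
            raise ValueError("mfactor must be >= 0")


def _inside_any(points: np.ndarray, spheres: list[Sphere], skip: int) -> np.ndarray:
    """Strictly-inside test against every sphere except `skip`.

    Strict inequality keeps points lying exactly on another sphere's
    surface, which stabilizes tangent-sphere configurations.
    """
    pts = np.atleast_2d(points)
    inside = np.zeros(len(pts), dtype=bool)
    for j, s in enumerate(spheres):
        if j == skip:
            continue
        d2 = np.einsum("ij,ij->i", pts - s.center, pts - s.center)
        inside |= d2 < s.radius**2
    return inside


def _secondary_split(t: Tessera, sphere: Sphere) -> list[Tessera]:
    """One midpoint 4-split of a tessera, children projected to the sphere."""
    c, r = sphere.center, sphere.radius
    v = t.vertices
    mids = np.empty((3, 3))
    for k, (i, j) in enumerate(((0, 1), (1, 2), (2, 0))):
        m = 0.5 * (v[i] + v[j]) - c
        mids[k] = c + r * m / np.linalg.norm(m)
    children = [
        np.array([v[0], mids[0], mids[2]]),
        np.array([v[1], mids[1], mids[0]]),
        np.array([v[2], mids[2], mids[1]]),
        np.array([mids[0], mids[1], mids[2]]),
    ]
    out = []
    for tri in children:
        u = (tri - c) / r
        area = float(spherical_triangle_areas(u[0], u[1], u[2])) * r**2
        ctr = u.mean(axis=0)
        ctr /= np.linalg.norm(ctr)
        out.append(
            Tessera(
                center=c + r * ctr,
                area=area,
                normal=ctr,
                vertices=tri,
                sphere_id=t.sphere_id,
            )
        )
    return out


def build_vdw_cavity(
    spheres: list[Sphere], level: "str | TessLevel" = "fine"
) -> Cavity:
    """Tessellate the union-of-spheres surface.

    Tesserae fully exposed are kept whole; tesserae fully buried inside
    another sphere are dropped; boundary tesserae get one secondary
    4-split and exposed secondary tesserae survive as independent segments.
    """
    if not spheres:
        raise ValueError("cavity requires at least one sphere")
    lvl = get_level(level)
    segments: list[Segment] = []
    for i, sph in enumerate(spheres):
        for t in tessellate_sphere(sph.center, sph.radius, lvl, sphere_id=i):
            pts = np.vstack([t.vertices, t.center])
            status = _inside_any(pts, spheres, skip=i)
            if not status.any():
                segments.append(
                    Segment(t.center, t.area, t.normal, sphere_id=i)
                )
            elif status.all():
                continue
            else:
                for child in _secondary_split(t, sph):
                    if not _inside_any(child.center, spheres, skip=i)[0]:
                        segments.append(
                            Segment(
                                child.center, child.area, child.normal, sphere_id=i
                            )
                        )
    if not segments:
        raise ValueError("all surface tesserae are buried; degenerate sphere set")
    area, volume = _area_volume(segments)
    return Cavity(spheres=list(spheres), segments=segments, area=area, volume=volume)


def gepol_add_spheres(
    atom_spheres: list[Sphere],
    rsolv: float,
    ofac: float = 0.8,
    rmin: float = 0.5,
    max_passes: int = 30,
) -> list[Sphere]:
    """Add auxiliary spheres filling solvent-inaccessible interstices.

    For every pair of spheres whose gap the probe cannot pass and whose
    mutual overlap is below `ofac`, a new sphere is placed on the pair axis
    at the plane of closest probe approach: with the probe simultaneously
    tangent to both spheres its center sits at axial distance
    x = (d² + (R₁+rs)² − (R₂+rs)²)/2d from the first sphere and height
    h = √((R₁+rs)² − x²) off the axis; the auxiliary sphere is centered at
    x with radius h − rs, i.e. tangent to the rolling probe.  Candidates
    with radius < rmin or engulfed by an existing sphere are discarded, and
    the scan repeats over newly created spheres until no additions remain.
    """
    if rsolv <= 0:
        raise ValueError("rsolv must be positive")
    spheres = list(atom_spheres)
    for _ in range(max_passes):
        added = False
        n = len(spheres)
        for i in range(n):
            for j in range(i + 1, n):
                a, b = spheres[i], spheres[j]
                if a.radius < b.radius:
                    a, b = b, a
                d = float(np.linalg.norm(b.center - a.center))
                if d < 1e-12:
                    continue
                if d >= a.radius + b.radius + 2.0 * rsolv:
                    continue  # the probe passes between the spheres
                overlap = (a.radius + b.radius - d) / (2.0 * b.radius)
                if overlap >= ofac:
                    continue  # deeply fused; no interstice to fill
                ra, rb = a.radius + rsolv, b.radius + rsolv
                x = (d * d + ra * ra - rb * rb) / (2.0 * d)
                h2 = ra * ra - x * x
                if h2 <= 0.0:
                    continue  # no common tangent probe position
                r_new = float(np.sqrt(h2)) - rsolv
                if r_new < rmin:
                    continue
                c_new = a.center + x * (b.center - a.center) / d
                engulfed = any(
                    np.linalg.norm(c_new - s.center) + r_new <= s.radius + 1e-9
                    for s in spheres
                )
                if engulfed:
                    continue
                spheres.append(Sphere(c_new, r_new, origin=AUXILIARY))
                added = True
        if not added:
            break
    return spheres


def build_ses_cavity(
    atom_spheres: list[Sphere], params: CavityParams
) -> Cavity:
    """Approximate SES: auxiliary spheres, clipping, then segment merging."""
    aug = gepol_add_spheres(atom_spheres, params.rsolv, params.ofac, params.rmin)
    cav = build_vdw_cavity(aug, params.level)
    d_min = compute_d_min(params.level, params.rsolv, params.mfactor)
    merged = merge_segments(cav.segments, d_min)
    area, volume = _area_volume(merged)
    return Cavity(spheres=aug, segments=merged, area=area, volume=volume)


def build_cavity(atom_spheres: list[Sphere], params: CavityParams) -> Cavity:
    """Build a vdW or SES cavity per `params`; merging applies to both."""
    if params.cavity_type == "ses":
        return build_ses_cavity(atom_spheres, params)
    cav = build_vdw_cavity(atom_spheres, params.level)
    d_min = compute_d_min(params.level, params.rsolv, params.mfactor)
    merged = merge_segments(cav.segments, d_min)
    area, volume = _area_volume(merged)
    return Cavity(spheres=cav.spheres, segments=merged, area=area, volume=volume)


def _area_volume(segments: list[Segment]) -> tuple[float, float]:
    areas = np.array([s.area for s in segments])
    centers = np.array([s.center for s in segments])
    normals = np.array([s.normal for s in segments])
    area = float(areas.sum())
    # divergence theorem: V = (1/3) ∮ r·n dS, origin-independent when closed
    volume = float(np.sum(areas * np.einsum("ij,ij->i", centers, normals)) / 3.0)
    return area, volume


def compute_area_volume(cavity: Cavity) -> tuple[float, float]:
    """Total surface area (Å²) and enclosed volume (Å³) of the cavity."""
    if not cavity.segments:
        raise ValueError("cavity has no segments")
    return _area_volume(cavity.segments)


def compute_d_min(
    level: "str | TessLevel", rsolv: float, mfactor: float
) -> float:
    """Minimum expected inter-segment distance for the merge step (Å).

    Half the mean edge length of a *secondary* (once more subdivided)
    tessera on a probe-sized sphere, scaled by `mfactor`: linear in
    mfactor (0 disables merging) and shrinking with refinement.  Secondary
    tesserae are the smallest legitimate segments the clipping step can
    produce, so any pair closer than half their spacing is a boundary
    artifact; a larger reference length would start merging regular
    neighbors and degrade the surface quadrature.
    """
    if mfactor < 0:
        raise ValueError("mfactor must be >= 0")
    from .tessellation import subdivide

    mesh = subdivide(unit_mesh(level), 1)
    edges = np.array(sorted(mesh.edges()))
    lengths = np.linalg.norm(
        mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1
    )
    return float(mfactor * 0.5 * lengths.mean() * rsolv)


def merge_segments(segments: list[Segment], d_min: float) -> list[Segment]:
    """Merge segments closer than d_min by transitive closure.

    Merged segments sit at the area-weighted centroid of their constituents
    with summed areas and a renormalized area-weighted normal.  The pass is
    repeated on the merged set until every pairwise center distance is at
    least d_min, so the contract holds even when centroids of distinct
    groups land close together.
    """
    if d_min < 0:
        raise ValueError("d_min must be >= 0")
    if d_min == 0 or len(segments) < 2:
        return list(segments)
    segs = list(segments)
    while True:
        centers = np.array([s.center for s in segs])
        tree = cKDTree(centers)
        pairs = [
            (i, j)
            for i, j in tree.query_pairs(d_min)
            if np.linalg.norm(centers[i] - centers[j]) < d_min
        ]
        if not pairs:
            return segs
        parent = list(range(len(segs)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in pairs:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
        groups: dict[int, list[int]] = {}
        for k in range(len(segs)):
            groups.setdefault(find(k), []).append(k)
        merged: list[Segment] = []
        for members in groups.values():
            if len(members) == 1:
                merged.append(segs[members[0]])
                continue
            parts = [segs[k] for k in members]
            w = np.array([p.area for p in parts])
            total = float(w.sum())
            center = np.average([p.center for p in parts], axis=0, weights=w)
            nvec = np.average([p.normal for p in parts], axis=0, weights=w)
            nn = np.linalg.norm(nvec)
            if nn < 1e-12:  # opposing normals cancelled; keep dominant patch
                nvec = parts[int(np.argmax(w))].normal
            else:
                nvec = nvec / nn
            biggest = parts[int(np.argmax(w))]
            merged.append(
                Segment(
                    center=center,
                    area=total,
                    normal=nvec,
                    sphere_id=biggest.sphere_id,
                    merged_count=sum(p.merged_count for p in parts),
                )
            )
        segs = merged
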