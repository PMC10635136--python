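"""Explicit 3-D construction of Caspar-Klug capsid lattices.

The construction wraps a hexagonal lattice onto the 20 flat faces of a
regular icosahedron.  Each face is an equilateral triangle whose three
corners are pentamer positions; in lattice coordinates the corners are
``A = (0, 0)``, ``B = (h, k)`` and ``C = (-k, h + k)`` (the 60-degree
rotation of B), so the face covers exactly T unit triangles.  Every
hexagonal-lattice point falling inside or on the triangle maps to a
capsomer site via exact rational barycentric coordinates — membership
tests are integer comparisons, never epsilon comparisons — and sites
shared between adjacent faces (edge and vertex points) are merged by a
spatial hash at a tolerance of 1e-9 edge lengths.

The capsid is kept faceted (sites on the flat faces, not projected to a
sphere): on the facets the icosahedral symmetry is exact up to floating
rounding, which is what makes the brute-force axis classification in
:mod:`capsidlattice.symmetry_census` a trustworthy oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal

import numpy as np
from scipy.spatial import Delaunay

from .errors import InvalidStepError, StructureError
from .hexlattice import AxialStep, canonicalize, t_number

__all__ = [
    "Icosahedron",
    "SymmetryAxis",
    "CapsomerSite",
    "CapsidLattice",
    "FacetMesh",
    "build_icosahedron",
    "symmetry_axes",
    "build_capsid",
    "facet_mesh",
]

Handedness = Literal["laevo", "dextro"]

#: symmetry classes a capsomer site can belong to
FIVEFOLD = "fivefold_vertex"
THREEFOLD = "global_threefold"
TWOFOLD = "global_twofold"
GENERAL = "general"

_CLASS_TO_ORDER = {FIVEFOLD: 5, THREEFOLD: 3, TWOFOLD: 2, GENERAL: 0}


@dataclass(frozen=True)
class Icosahedron:
    """Fixed-orientation regular icosahedron with unit circumradius.

    Vertices are the normalized cyclic permutations of (0, ±1, ±φ),
    which places the 15 two-fold axes on the coordinate axes and planes.
    """

    vertices: np.ndarray  # (12, 3) unit vectors
    faces: np.ndarray  # (20, 3) vertex indices, outward winding
    edges: np.ndarray  # (30, 2) vertex index pairs, i < j

    @property
    def edge_length(self) -> float:
        a, b = self.edges[0]
        return float(np.linalg.norm(self.vertices[a] - self.vertices[b]))


@dataclass(frozen=True)
class SymmetryAxis:
    """A global icosahedral rotation axis, identified with its negation.

    ``order`` is 5 (vertex axes), 3 (face-centroid axes) or
    2 (edge-midpoint axes).
    """

    order: int
    direction: np.ndarray  # unit vector, canonical sign


@dataclass(frozen=True)
class CapsomerSite:
    """One capsomer: a pentamer (at an icosahedron vertex) or a hexamer.

    ``lattice_coords`` records the face index and the integer hexagonal
    coordinates ``(i, j)`` of the site on that face's net (the face it
    was first generated on, for boundary sites shared between faces).
    ``symmetry_class`` is assigned from exact lattice predicates at
    build time.
    """

    position: np.ndarray  # (3,)
    face_index: int
    lattice_coords: tuple[int, int]
    kind: Literal["pentamer", "hexamer"]
    symmetry_class: str

    @property
    def expected_axis_order(self) -> int:
        return _CLASS_TO_ORDER[self.symmetry_class]


@dataclass(frozen=True)
class CapsidLattice:
    """All capsomer sites of one Caspar-Klug capsid.

    Site counts satisfy the icosahedral bookkeeping: 12 pentamers,
    10(T-1) hexamers, 10T+2 capsomers in total.
    """

    step: AxialStep
    T: int
    radius: float
    handedness: Handedness
    sites: tuple[CapsomerSite, ...]
    icosahedron: Icosahedron = field(repr=False)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites])

    @property
    def pentamers(self) -> list[CapsomerSite]:
        return [s for s in self.sites if s.kind == "pentamer"]

    @property
    def hexamers(self) -> list[CapsomerSite]:
        return [s for s in self.sites if s.kind == "hexamer"]


@dataclass(frozen=True)
class FacetMesh:
    """Closed triangulated surface of the faceted capsid; its vertex set
    is exactly the capsomer positions."""

    vertices: np.ndarray  # (N, 3)
    triangles: np.ndarray  # (M, 3) vertex indices, outward winding

    @property
    def euler_characteristic(self) -> int:
        edges = set()
        for a, b, c in self.triangles:
            for u, v in ((a, b), (b, c), (c, a)):
                edges.add((min(u, v), max(u, v)))
        return len(self.vertices) - len(edges) + len(self.triangles)


def build_icosahedron() -> Icosahedron:
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    verts = []
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            verts.append((0.0, s1, s2 * phi))
            verts.append((s1, s2 * phi, 0.0))
            verts.append((s2 * phi, 0.0, s1))
    vertices = np.array(sorted(verts))
    vertices /= np.linalg.norm(vertices[0])

    d2 = np.sum((vertices[:, None, :] - vertices[None, :, :]) ** 2, axis=-1)
    edge2 = np.min(d2[d2 > 1e-12])
    adjacent = np.abs(d2 - edge2) < 1e-9
    edges = np.array([(i, j) for i, j in combinations(range(12), 2) if adjacent[i, j]])

    faces = []
    for i, j, k in combinations(range(12), 3):
        if adjacent[i, j] and adjacent[j, k] and adjacent[i, k]:
            tri = [i, j, k]
            # outward winding: normal points away from the origin
            n = np.cross(vertices[tri[1]] - vertices[tri[0]],
                         vertices[tri[2]] - vertices[tri[0]])
            if np.dot(n, vertices[tri].mean(axis=0)) < 0:
                tri = [i, k, j]
            faces.append(tri)
    faces = np.array(faces)
    if len(faces) != 20 or len(edges) != 30:  # pragma: no cover
        raise StructureError("icosahedron construction failed")
    return Icosahedron(vertices=vertices, faces=faces, edges=edges)


def _canonical_direction(v: np.ndarray) -> np.ndarray:
    v = v / np.linalg.norm(v)
    # identify v with -v: flip so the first component above rounding is positive
    for x in v:
        if abs(x) > 1e-9:
            return v if x > 0 else -v
    raise StructureError("zero axis direction")  # pragma: no cover


def symmetry_axes(ico: Icosahedron) -> list[SymmetryAxis]:
    """The 31 rotation axes of the icosahedron: 6 five-fold through
    opposite vertices, 10 three-fold through opposite face centroids,
    15 two-fold through opposite edge midpoints."""
    if ico.vertices.shape != (12, 3) or ico.faces.shape != (20, 3):
        raise StructureError("malformed icosahedron")
    axes: list[SymmetryAxis] = []
    seen: set[tuple[int, tuple[float, ...]]] = set()

    def add(order: int, direction: np.ndarray) -> None:
        d = _canonical_direction(direction)
        key = (order, tuple(np.round(d, 9)))
        if key not in seen:
            seen.add(key)
            axes.append(SymmetryAxis(order=order, direction=d))

    for v in ico.vertices:
        add(5, v)
    for f in ico.faces:
        add(3, ico.vertices[f].mean(axis=0))
    for i, j in ico.edges:
        add(2, (ico.vertices[i] + ico.vertices[j]) / 2.0)

    counts = {o: sum(1 for a in axes if a.order == o) for o in (5, 3, 2)}
    if counts != {5: 6, 3: 10, 2: 15}:  # pragma: no cover
        raise StructureError(f"unexpected axis counts {counts}")
    return axes


def _face_lattice_points(h: int, k: int):
    """Integer lattice points of one face in exact scaled barycentric
    coordinates.

    Returns arrays ``(i, j, v_num, w_num)`` where the barycentric
    coordinates of point ``(i, j)`` relative to the face corners
    A=(0,0), B=(h,k), C=(-k,h+k) are ``v = v_num/T`` and ``w = w_num/T``
    (and ``u = 1 - v - w``).  Membership (``u, v, w >= 0``) is an exact
    integer test.
    """
    T = h * h + h * k + k * k
    i_lo, i_hi = min(0, h, -k), max(0, h, -k)
    j_lo, j_hi = min(0, k, h + k), max(0, k, h + k)
    i, j = np.meshgrid(np.arange(i_lo, i_hi + 1), np.arange(j_lo, j_hi + 1),
                       indexing="ij")
    i, j = i.ravel(), j.ravel()
    v_num = i * (h + k) + j * k
    w_num = h * j - k * i
    mask = (v_num >= 0) & (w_num >= 0) & (v_num + w_num <= T)
    return i[mask], j[mask], v_num[mask], w_num[mask]


def _exact_symmetry_class(v_num: int, w_num: int, T: int) -> tuple[str, str]:
    """Site kind and symmetry class from exact lattice predicates.

    Corners of the face triangle are pentamers on 5-fold axes; the face
    centroid (v = w = 1/3, a lattice point iff h ≡ k mod 3, i.e. 3 | T)
    lies on a global 3-fold axis; edge midpoints (a lattice point iff h
    and k are both even) lie on global 2-fold axes; everything else is
    in general position.
    """
    u_num = T - v_num - w_num
    if (v_num, w_num) in ((0, 0), (T, 0), (0, T)):
        return "pentamer", FIVEFOLD
    if T % 3 == 0 and v_num == w_num == T // 3:
        return "hexamer", THREEFOLD
    if T % 2 == 0:
        half = T // 2
        if (u_num, v_num, w_num) in ((half, half, 0), (half, 0, half), (0, half, half)):
            return "hexamer", TWOFOLD
    return "hexamer", GENERAL


class _SpatialHash:
    """Merge 3-D points that coincide within ``tol`` (grid hash with
    neighbor-cell lookup, robust to points straddling a cell border)."""

    def __init__(self, tol: float):
        self.tol = tol
        self.cells: dict[tuple[int, int, int], list[tuple[np.ndarray, int]]] = {}

    def find_or_insert(self, p: np.ndarray, index: int) -> int:
        """Return the index of a previously inserted coincident point,
        or insert ``p`` under ``index`` and return ``index``."""
        c = tuple(int(math.floor(x / self.tol)) for x in p)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for q, idx in self.cells.get((c[0] + dx, c[1] + dy, c[2] + dz), ()):
                        if np.sum((p - q) ** 2) <= self.tol * self.tol:
                            return idx
        self.cells.setdefault(c, []).append((p, index))
        return index


def build_capsid(step, radius: float = 300.0,
                 handedness: Handedness = "laevo") -> CapsidLattice:
    """Construct the full capsomer lattice for lattice step ``(h, k)``.

    The step is canonicalized (``h >= k >= 0``); ``radius`` is the
    center-to-vertex distance in arbitrary length units; ``handedness``
    selects between the two mirror-image wrappings of a chiral lattice
    (``laevo`` is the default, ``dextro`` mirrors through the yz-plane,
    which maps the icosahedron scaffold to itself).
    """
    cstep = canonicalize(step)
    if radius <= 0:
        raise InvalidStepError(f"radius must be positive, got {radius!r}")
    if handedness not in ("laevo", "dextro"):
        raise InvalidStepError(f"handedness must be 'laevo' or 'dextro', got {handedness!r}")
    h, k = cstep
    T = t_number(cstep)

    ico = build_icosahedron()
    verts = ico.vertices * radius
    merge_tol = 1e-9 * ico.edge_length * radius

    sites: list[CapsomerSite] = []
    dedup = _SpatialHash(merge_tol)
    for f, (a, b, c) in enumerate(ico.faces):
        VA, VB, VC = verts[a], verts[b], verts[c]
        ii, jj, vv, ww = _face_lattice_points(h, k)
        pos = (VA[None, :]
               + np.outer(vv / T, VB - VA)
               + np.outer(ww / T, VC - VA))
        if handedness == "dextro":
            pos = pos * np.array([-1.0, 1.0, 1.0])
        for n in range(len(ii)):
            p = pos[n]
            if dedup.find_or_insert(p, len(sites)) == len(sites):
                kind, sym = _exact_symmetry_class(int(vv[n]), int(ww[n]), T)
                sites.append(CapsomerSite(
                    position=p,
                    face_index=f,
                    lattice_coords=(int(ii[n]), int(jj[n])),
                    kind=kind,
                    symmetry_class=sym,
                ))

    n_pent = sum(1 for s in sites if s.kind == "pentamer")
    n_hex = len(sites) - n_pent
    if n_pent != 12 or n_hex != 10 * (T - 1):
        raise StructureError(
            f"site bookkeeping failed for T={T}: "
            f"{n_pent} pentamers, {n_hex} hexamers (expected 12 and {10 * (T - 1)})"
        )
    return CapsidLattice(step=cstep, T=T, radius=float(radius),
                         handedness=handedness, sites=tuple(sites),
                         icosahedron=ico)


def facet_mesh(capsid: CapsidLattice) -> FacetMesh:
    """Closed, outward-wound triangulation of the faceted capsid surface
    with one mesh vertex per capsomer site.

    Each face's sites are triangulated with a Delaunay triangulation in
    exact integer lattice coordinates (all determinants fit in double
    precision, so collinear boundary points are handled exactly), then
    glued along shared edges via the same coincidence tolerance used for
    site deduplication.
    """
    h, k = capsid.step
    T = capsid.T
    ico = capsid.icosahedron
    verts = ico.vertices * capsid.radius
    merge_tol = 1e-9 * ico.edge_length * capsid.radius

    positions = capsid.positions
    lookup = _SpatialHash(merge_tol)
    for idx, p in enumerate(positions):
        lookup.find_or_insert(p, idx)

    mirror = np.array([-1.0, 1.0, 1.0]) if capsid.handedness == "dextro" else None
    triangles: list[tuple[int, int, int]] = []
    for a, b, c in ico.faces:
        VA, VB, VC = verts[a], verts[b], verts[c]
        _, _, vv, ww = _face_lattice_points(h, k)
        pos = (VA[None, :]
               + np.outer(vv / T, VB - VA)
               + np.outer(ww / T, VC - VA))
        if mirror is not None:
            pos = pos * mirror
        global_idx = np.array([lookup.find_or_insert(p, -1) for p in pos])
        if np.any(global_idx < 0):  # pragma: no cover
            raise StructureError("face site missing from capsid site set")
        if len(vv) == 3:
            local_tris = np.array([[0, 1, 2]])
        else:
            local_tris = Delaunay(np.column_stack([vv, ww]).astype(float)).simplices
        for tri in global_idx[local_tris]:
            p0, p1, p2 = positions[tri]
            n = np.cross(p1 - p0, p2 - p0)
            if np.dot(n, (p0 + p1 + p2)) < 0:
                tri = tri[::-1]
            triangles.append(tuple(int(x) for x in tri))

    mesh = FacetMesh(vertices=positions, triangles=np.array(triangles))
    if mesh.euler_characteristic != 2:
        raise StructureError(
            f"facet mesh is not a closed surface (chi={mesh.euler_characteristic})"
        )
    return mesh
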