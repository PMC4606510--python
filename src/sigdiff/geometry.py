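"""Tagged simplex meshes of cell- and tissue-scale signaling geometries.

The spatially resolved domain is always the region where molecules diffuse:
the cytoplasmic shell of a single cell (outer shape minus the nucleus, which
is a well-mixed compartment and is *not* meshed), or the extracellular space
of a multicellular lattice (a box minus spherical cell holes).  Boundary
facets carry integer tags so that Robin couplings can be attached to the
outer membrane, the nuclear interface, or individual cell surfaces.

Tag conventions
---------------
``TAG_MEMBRANE = 1``  outer membrane (Gamma_m)
``TAG_NUCLEUS = 2``   nuclear interface (Gamma_n)
``TAG_BOX = 3``       outer box boundary of a lattice cutout
``CELL_TAG_BASE + k`` surface of cell ``k`` in a lattice

All coordinates are micrometres.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

TAG_MEMBRANE = 1
TAG_NUCLEUS = 2
TAG_BOX = 3
CELL_TAG_BASE = 100

_FACTORIAL = {1: 1.0, 2: 2.0, 3: 6.0}


class MeshError(ValueError):
    """Base class for geometry/mesh failures."""


class InfeasibleGeometryError(MeshError):
    """The requested geometry violates its own invariants (e.g. nucleus touching membrane)."""


class MeshingError(MeshError):
    """The mesher itself failed on a feasible specification."""


# ---------------------------------------------------------------------------
# Mesh container
# ---------------------------------------------------------------------------


@dataclass
class Mesh:
    """Simplex mesh with tagged boundary facets.

    ``nodes``:  (n_nodes, dim) float coordinates in um.
    ``elements``: (n_elem, dim+1) int connectivity (triangles or tetrahedra),
        oriented so all signed measures are positive.
    ``boundary_facets``: (n_facets, dim) int connectivity of boundary facets
        (segments in 2D, triangles in 3D).
    ``facet_tags``: (n_facets,) int, one tag per facet.
    ``region_tags``: optional per-element int labels.
    ``metadata``: free-form JSON-serializable dict (lattice cell info lives here).
    """

    nodes: np.ndarray
    elements: np.ndarray
    boundary_facets: np.ndarray
    facet_tags: np.ndarray
    dim: int
    region_tags: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_volumes(self) -> np.ndarray:
        """Measures (areas in 2D, volumes in 3D) of all elements; positive."""
        vecs = (
            self.nodes[self.elements[:, 1:]]
            - self.nodes[self.elements[:, :1]]
        )
        dets = np.linalg.det(vecs)
        return dets / _FACTORIAL[self.dim]

    def facet_areas(self) -> np.ndarray:
        """Measures of boundary facets (lengths in 2D, areas in 3D)."""
        pts = self.nodes[self.boundary_facets]
        if self.dim == 2:
            return np.linalg.norm(pts[:, 1] - pts[:, 0], axis=1)
        cross = np.cross(pts[:, 1] - pts[:, 0], pts[:, 2] - pts[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def boundary_tags(self) -> list[int]:
        return sorted(int(t) for t in np.unique(self.facet_tags))

    def volume(self) -> float:
        return float(self.element_volumes().sum())

    def surface_area(self, tag: int | None = None) -> float:
        areas = self.facet_areas()
        if tag is None:
            return float(areas.sum())
        return float(areas[self.facet_tags == tag].sum())

    def validate(self) -> None:
        if self.nodes.ndim != 2 or self.nodes.shape[1] != self.dim:
            raise MeshError("node array shape inconsistent with dim")
        if self.elements.max() >= self.n_nodes or self.elements.min() < 0:
            raise MeshError("element connectivity references missing nodes")
        vols = self.element_volumes()
        if np.any(vols <= 0):
            bad = int(np.argmin(vols))
            raise MeshError(
                f"element {bad} has nonpositive measure {vols[bad]:.3e}"
            )
        if self.facet_tags.shape[0] != self.boundary_facets.shape[0]:
            raise MeshError("every boundary facet must carry exactly one tag")
        # the tagged facets must be exactly the topological boundary
        topo = _boundary_facets(self.elements, self.dim)
        ours = _canonical_facet_set(self.boundary_facets)
        theirs = _canonical_facet_set(topo)
        if ours != theirs:
            raise MeshError("tagged facets do not coincide with the topological boundary")

    def average_edge_length(self) -> float:
        e = self.edges()
        return float(
            np.linalg.norm(self.nodes[e[:, 0]] - self.nodes[e[:, 1]], axis=1).mean()
        )

    def edges(self) -> np.ndarray:
        pairs = list(itertools.combinations(range(self.dim + 1), 2))
        e = np.vstack([self.elements[:, p] for p in pairs])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def boundary_nodes(self, tag: int) -> np.ndarray:
        """Sorted node indices lying on facets with the given tag."""
        sel = self.boundary_facets[self.facet_tags == tag]
        if sel.size == 0:
            raise MeshError(f"no boundary facets carry tag {tag}")
        return np.unique(sel)

    def canonical_connectivity(self) -> tuple:
        """Connectivity invariant under node re-indexing (for format round-trips).

        Nodes are re-labelled by lexicographic coordinate order (rounded to
        1e-9 um); element and facet rows are sorted.  Two meshes describing
        the same discretization compare equal.
        """
        key = np.round(self.nodes, 9)
        order = np.lexsort(key.T[::-1])
        rank = np.empty(self.n_nodes, dtype=int)
        rank[order] = np.arange(self.n_nodes)

        def canon(conn):
            c = np.sort(rank[conn], axis=1)
            return c[np.lexsort(c.T[::-1])]

        facets = rank[self.boundary_facets]
        facets_sorted = np.sort(facets, axis=1)
        forder = np.lexsort(facets_sorted.T[::-1])
        return (
            canon(self.elements).tobytes(),
            facets_sorted[forder].tobytes(),
            self.facet_tags[forder].tobytes(),
        )


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass
class Extensions:
    """Cylindrical cytoplasmic extensions (filopodia) grafted on a sphere cell."""

    count: int = 2
    length: float = 20.0
    radius: float = 1.0
    directions: tuple | None = None  # unit vectors; default +/- x

    def unit_directions(self, dim: int) -> np.ndarray:
        if self.directions is not None:
            d = np.asarray(self.directions, dtype=float)
        else:
            d = np.zeros((self.count, dim))
            for i in range(self.count):
                d[i, 0] = 1.0 if i % 2 == 0 else -1.0
        if d.shape[0] != self.count:
            raise InfeasibleGeometryError("directions do not match extension count")
        norms = np.linalg.norm(d, axis=1, keepdims=True)
        return d / norms


@dataclass
class CellGeometrySpec:
    """Single-cell geometry: cytoplasmic shell between membrane and nucleus.

    ``kind``: ``sphere_shell`` (sphere minus concentric spherical nucleus),
    ``box_shell`` (box minus centered box nucleus) or ``extended_shell``
    (sphere shell with cylindrical extensions, voxel-meshed).
    Dimensions in um.  Defaults are plausible cell scales (they are
    configuration stand-ins, not measured values): a sphere cell of radius
    5 with a large nucleus of radius 3; a 30 x 20 x 10 box cell with a
    10 x 8 x 6 nucleus; extensions of length 20 and radius 1.
    """

    kind: str = "sphere_shell"
    outer: float | tuple = 5.0
    nucleus: float | tuple = 3.0
    extensions: Extensions | None = None
    target_h: float = 1.0
    dim: int = 3

    def __post_init__(self):
        if self.kind not in ("sphere_shell", "box_shell", "extended_shell"):
            raise InfeasibleGeometryError(f"unknown geometry kind {self.kind!r}")
        if self.target_h <= 0:
            raise InfeasibleGeometryError("target_h must be positive")
        if self.dim not in (2, 3):
            raise InfeasibleGeometryError("dim must be 2 or 3")
        if self.kind in ("sphere_shell", "extended_shell"):
            if not np.isscalar(self.outer) or not np.isscalar(self.nucleus):
                raise InfeasibleGeometryError("sphere-type shells take scalar radii")
            if not 0 < self.nucleus < self.outer:
                raise InfeasibleGeometryError(
                    f"nucleus radius {self.nucleus} must lie strictly inside the "
                    f"outer radius {self.outer}"
                )
        else:
            out = np.atleast_1d(np.asarray(self.outer, dtype=float))
            nuc = np.atleast_1d(np.asarray(self.nucleus, dtype=float))
            if out.size != self.dim or nuc.size != self.dim:
                raise InfeasibleGeometryError("box shells take per-axis edge lengths")
            if np.any(nuc <= 0) or np.any(nuc >= out):
                raise InfeasibleGeometryError("box nucleus must fit strictly inside the cell")
        if self.kind == "extended_shell":
            ext = self.extensions or Extensions()
            if ext.radius >= self.outer:
                raise InfeasibleGeometryError("extension radius must be below the cell radius")
            object.__setattr__(self, "extensions", ext)


@dataclass
class LatticeSpec:
    """Cubic lattice cutout of a lymph node: box minus spherical T cells.

    ``spacing`` is center-to-center (um) and must exceed the cell diameter.
    Cell types are drawn without replacement with a seeded generator;
    counts are ``round(fraction * N)``.
    """

    grid: tuple = (5, 5, 5)
    cell_radius: float = 4.0
    spacing: float = 10.0
    fraction_secreting: float = 0.25
    fraction_regulatory: float = 0.0
    rng_seed: int = 0
    target_h: float = 2.5

    def __post_init__(self):
        if len(self.grid) != 3 or any(int(n) < 1 for n in self.grid):
            raise InfeasibleGeometryError("grid must be three positive integers")
        if self.spacing <= 2.0 * self.cell_radius:
            raise InfeasibleGeometryError(
                f"spacing {self.spacing} must exceed the cell diameter "
                f"{2 * self.cell_radius} (cells may not overlap)"
            )
        if not (0.0 <= self.fraction_secreting <= 1.0 and 0.0 <= self.fraction_regulatory <= 1.0):
            raise InfeasibleGeometryError("fractions must lie in [0, 1]")
        if self.fraction_secreting + self.fraction_regulatory > 1.0 + 1e-12:
            raise InfeasibleGeometryError("secreting + regulatory fractions exceed 1")
        if self.target_h <= 0:
            raise InfeasibleGeometryError("target_h must be positive")

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.grid))


def assign_cell_types(n_cells: int, fraction_secreting: float,
                      fraction_regulatory: float, seed: int) -> list[str]:
    """Seeded draw without replacement; counts are round(fraction * N)."""
    n_sec = int(round(fraction_secreting * n_cells))
    n_reg = int(round(fraction_regulatory * n_cells))
    if n_sec + n_reg > n_cells:
        raise InfeasibleGeometryError("requested more typed cells than cells")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_cells)
    types = np.array(["responder"] * n_cells, dtype=object)
    types[perm[:n_sec]] = "secreting"
    types[perm[n_sec:n_sec + n_reg]] = "regulatory"
    return [str(t) for t in types]


# ---------------------------------------------------------------------------
# Low-level helpers
# ---------------------------------------------------------------------------


def _fix_orientation(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    vecs = nodes[elements[:, 1:]] - nodes[elements[:, :1]]
    dets = np.linalg.det(vecs)
    flip = dets < 0
    if np.any(flip):
        elements = elements.copy()
        elements[flip, -2], elements[flip, -1] = (
            elements[flip, -1].copy(),
            elements[flip, -2].copy(),
        )
    return elements


def _facet_index_sets(dim: int):
    return list(itertools.combinations(range(dim + 1), dim))


def _boundary_facets(elements: np.ndarray, dim: int) -> np.ndarray:
    faces = np.vstack([elements[:, idx] for idx in _facet_index_sets(dim)])
    sfaces = np.sort(faces, axis=1)
    _, inv, counts = np.unique(sfaces, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def _canonical_facet_set(facets: np.ndarray) -> set:
    return set(map(tuple, np.sort(facets, axis=1).tolist()))


def _prune_nodes(nodes: np.ndarray, elements: np.ndarray):
    used = np.unique(elements)
    remap = -np.ones(nodes.shape[0], dtype=int)
    remap[used] = np.arange(used.size)
    return nodes[used], remap[elements]


# ---- icosphere -------------------------------------------------------------


def _icosphere(subdiv: int):
    """Unit-sphere triangulation by icosahedron subdivision."""
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
            (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
            (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
            (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
            (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
            (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
        ],
        dtype=int,
    )
    verts = [tuple(v) for v in verts]
    cache: dict[tuple, int] = {}

    def midpoint(i, j):
        key = (min(i, j), max(i, j))
        if key in cache:
            return cache[key]
        m = np.array(verts[i]) + np.array(verts[j])
        m /= np.linalg.norm(m)
        verts.append(tuple(m))
        cache[key] = len(verts) - 1
        return cache[key]

    for _ in range(subdiv):
        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = np.array(new_faces, dtype=int)
        cache.clear()
    return np.array(verts), faces


# Prism-to-tet split (Dompierre et al. rotation table): after rotating the
# smallest global index to local position 0, the diagonal rule below yields a
# conforming 3-tet decomposition on shared quad faces.
_PRISM_ROTATIONS = [
    (0, 1, 2, 3, 4, 5),
    (1, 2, 0, 4, 5, 3),
    (2, 0, 1, 5, 3, 4),
    (3, 5, 4, 0, 2, 1),
    (4, 3, 5, 1, 0, 2),
    (5, 4, 3, 2, 1, 0),
]


def _split_prisms(prisms: np.ndarray) -> np.ndarray:
    tets = np.empty((prisms.shape[0] * 3, 4), dtype=int)
    for n, prism in enumerate(prisms):
        pos = int(np.argmin(prism))
        v = prism[list(_PRISM_ROTATIONS[pos])]
        if min(v[1], v[5]) < min(v[2], v[4]):
            local = [(0, 1, 2, 5), (0, 1, 5, 4), (0, 4, 5, 3)]
        else:
            local = [(0, 1, 2, 4), (0, 4, 2, 5), (0, 4, 5, 3)]
        for k, t in enumerate(local):
            tets[3 * n + k] = v[list(t)]
    return tets


def _sphere_shell_mesh_3d(r_out: float, r_in: float, h: float) -> Mesh:
    edge0 = 4.0 / math.sqrt(10.0 + 2.0 * math.sqrt(5.0))  # icosahedron edge, unit sphere
    subdiv = max(0, math.ceil(math.log2(edge0 * r_out / h))) if edge0 * r_out > h else 0
    verts, faces = _icosphere(subdiv)
    n_layers = max(1, math.ceil((r_out - r_in) / h))
    radii = np.linspace(r_in, r_out, n_layers + 1)
    n_surf = verts.shape[0]
    nodes = np.vstack([verts * r for r in radii])
    prisms = []
    for layer in range(n_layers):
        lo, hi = layer * n_surf, (layer + 1) * n_surf
        for a, b, c in faces:
            prisms.append((lo + a, lo + b, lo + c, hi + a, hi + b, hi + c))
    tets = _split_prisms(np.array(prisms, dtype=int))
    tets = _fix_orientation(nodes, tets)
    facets = _boundary_facets(tets, 3)
    centroids = nodes[facets].mean(axis=1)
    radius = np.linalg.norm(centroids, axis=1)
    tags = np.where(radius < 0.5 * (r_in + r_out), TAG_NUCLEUS, TAG_MEMBRANE)
    return Mesh(nodes, tets, facets, tags.astype(int), dim=3)


def _annulus_mesh_2d(r_out: float, r_in: float, h: float) -> Mesh:
    n_t = max(12, math.ceil(2.0 * math.pi * r_out / h))
    n_r = max(1, math.ceil((r_out - r_in) / h))
    radii = np.linspace(r_in, r_out, n_r + 1)
    theta = np.linspace(0.0, 2.0 * math.pi, n_t, endpoint=False)
    nodes = np.vstack(
        [np.column_stack([r * np.cos(theta), r * np.sin(theta)]) for r in radii]
    )

    def nid(i, j):  # layer i, angular j
        return i * n_t + (j % n_t)

    tris = []
    for i in range(n_r):
        for j in range(n_t):
            a, b = nid(i, j), nid(i, j + 1)
            c, d = nid(i + 1, j), nid(i + 1, j + 1)
            tris += [(a, b, d), (a, d, c)]
    tris = _fix_orientation(nodes, np.array(tris, dtype=int))
    facets = _boundary_facets(tris, 2)
    radius = np.linalg.norm(nodes[facets].mean(axis=1), axis=1)
    tags = np.where(radius < 0.5 * (r_in + r_out), TAG_NUCLEUS, TAG_MEMBRANE)
    return Mesh(nodes, tris, facets, tags.astype(int), dim=2)


# ---- structured voxel meshing ---------------------------------------------

_KUHN_PERMS = list(itertools.permutations(range(3)))


def _structured_mesh(axis_points: Sequence[np.ndarray],
                     keep: Callable[[np.ndarray], np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Simplex mesh of the cells of a tensor grid whose centers satisfy ``keep``.

    Uses the Kuhn (Freudenthal) split, which is conforming across identical
    cells, in 2D and 3D.
    """
    dim = len(axis_points)
    shape = tuple(len(p) for p in axis_points)
    grids = np.meshgrid(*axis_points, indexing="ij")
    nodes = np.column_stack([g.ravel() for g in grids])
    strides = np.array(
        [int(np.prod(shape[k + 1:])) for k in range(dim)], dtype=int
    )
    cells_shape = tuple(s - 1 for s in shape)
    idx = np.indices(cells_shape).reshape(dim, -1).T
    centers = np.column_stack(
        [0.5 * (axis_points[k][idx[:, k]] + axis_points[k][idx[:, k] + 1]) for k in range(dim)]
    )
    mask = np.asarray(keep(centers), dtype=bool)
    idx = idx[mask]
    if idx.shape[0] == 0:
        raise MeshingError("no grid cells fall inside the requested geometry")
    base = idx @ strides
    e = strides  # index offset of +1 along each axis
    if dim == 2:
        v00 = base
        v10 = base + e[0]
        v01 = base + e[1]
        v11 = base + e[0] + e[1]
        tris = np.concatenate(
            [
                np.column_stack([v00, v10, v11]),
                np.column_stack([v00, v11, v01]),
            ]
        )
        conn = tris
    else:
        corners = {}
        for cx in (0, 1):
            for cy in (0, 1):
                for cz in (0, 1):
                    corners[(cx, cy, cz)] = base + cx * e[0] + cy * e[1] + cz * e[2]
        tets = []
        for perm in _KUHN_PERMS:
            c = np.zeros(3, dtype=int)
            path = [tuple(c)]
            for axis in perm:
                c = c.copy()
                c[axis] = 1
                path.append(tuple(c))
            tets.append(np.column_stack([corners[p] for p in path]))
        conn = np.concatenate(tets)
    nodes, conn = _prune_nodes(nodes, conn)
    conn = _fix_orientation(nodes, conn)
    return nodes, conn


def _graded_axis(lo: float, hi: float, cuts: Sequence[float], h: float) -> np.ndarray:
    """1D grid on [lo, hi] containing all interior cut coordinates, spacing <= h."""
    brk = [lo] + sorted(c for c in cuts if lo < c < hi) + [hi]
    pts = [np.array([lo])]
    for a, b in zip(brk[:-1], brk[1:]):
        n = max(1, math.ceil((b - a) / h - 1e-12))
        pts.append(np.linspace(a, b, n + 1)[1:])
    return np.concatenate(pts)


def _box_shell_mesh(outer, nucleus, h: float, dim: int) -> Mesh:
    out = np.asarray(outer, dtype=float)
    nuc = np.asarray(nucleus, dtype=float)
    axis_points = [
        _graded_axis(-out[k] / 2, out[k] / 2, (-nuc[k] / 2, nuc[k] / 2), h)
        for k in range(dim)
    ]

    def keep(centers):
        inside_nuc = np.all(np.abs(centers) < nuc[:dim] / 2, axis=1)
        return ~inside_nuc

    nodes, conn = _structured_mesh(axis_points, keep)
    facets = _boundary_facets(conn, dim)
    centroids = nodes[facets].mean(axis=1)
    on_outer = np.any(
        np.isclose(np.abs(centroids), out[:dim] / 2, atol=1e-9 * max(out)), axis=1
    )
    tags = np.where(on_outer, TAG_MEMBRANE, TAG_NUCLEUS)
    return Mesh(nodes, conn, facets, tags.astype(int), dim=dim)


def _extended_shell_mesh(spec: CellGeometrySpec) -> Mesh:
    R, r_nuc = float(spec.outer), float(spec.nucleus)
    ext = spec.extensions or Extensions()
    h = spec.target_h
    if h >= (R - r_nuc) / 2:
        raise InfeasibleGeometryError(
            "target_h must be below half the shell thickness for voxel meshing"
        )
    dim = spec.dim
    dirs = ext.unit_directions(dim) if ext.count else np.zeros((0, dim))
    lo = np.full(dim, -R)
    hi = np.full(dim, R)
    for d in dirs:
        tip = d * (R + ext.length)
        lo = np.minimum(lo, tip - ext.radius)
        hi = np.maximum(hi, tip + ext.radius)
    axis_points = [_graded_axis(lo[k], hi[k], (), h) for k in range(dim)]

    def keep(centers):
        r = np.linalg.norm(centers, axis=1)
        inside = r <= R
        for d in dirs:
            axial = centers @ d
            perp = np.linalg.norm(centers - np.outer(axial, d), axis=1)
            inside |= (axial >= 0) & (axial <= R + ext.length) & (perp <= ext.radius)
        return inside & (r > r_nuc)

    nodes, conn = _structured_mesh(axis_points, keep)
    facets = _boundary_facets(conn, dim)
    radius = np.linalg.norm(nodes[facets].mean(axis=1), axis=1)
    tags = np.where(radius < 0.5 * (r_nuc + R), TAG_NUCLEUS, TAG_MEMBRANE)
    return Mesh(nodes, conn, facets, tags.astype(int), dim=dim)


# ---------------------------------------------------------------------------
# Public builders
# ---------------------------------------------------------------------------


def build_cell_mesh(spec: CellGeometrySpec) -> Mesh:
    """Mesh the cytoplasmic shell of a single cell.

    The nucleus interior is intentionally not meshed: it is represented only
    by its interface ``TAG_NUCLEUS``, matching the two-compartment structure
    in which the nucleus is a well-mixed ODE compartment.
    """
    if spec.kind == "sphere_shell":
        if spec.dim == 3:
            mesh = _sphere_shell_mesh_3d(float(spec.outer), float(spec.nucleus), spec.target_h)
        else:
            mesh = _annulus_mesh_2d(float(spec.outer), float(spec.nucleus), spec.target_h)
    elif spec.kind == "box_shell":
        mesh = _box_shell_mesh(spec.outer, spec.nucleus, spec.target_h, spec.dim)
    else:
        mesh = _extended_shell_mesh(spec)
    mesh.metadata["geometry"] = {
        "kind": spec.kind,
        "outer": spec.outer if np.isscalar(spec.outer) else list(spec.outer),
        "nucleus": spec.nucleus if np.isscalar(spec.nucleus) else list(spec.nucleus),
        "target_h": spec.target_h,
    }
    mesh.validate()
    return mesh


def build_lattice_mesh(spec: LatticeSpec) -> Mesh:
    """Mesh the extracellular space of a cubic cell lattice.

    Cells are spherical holes; each cell surface is tagged
    ``CELL_TAG_BASE + k`` and the outer box boundary ``TAG_BOX``.
    Cell-type labels (secreting / responder / regulatory) are drawn with a
    seeded generator and stored in ``mesh.metadata['cells']``.
    """
    n1, n2, n3 = (int(n) for n in spec.grid)
    s, r = spec.spacing, spec.cell_radius
    dims = (n1 * s, n2 * s, n3 * s)
    centers = np.array(
        [
            ((i + 0.5) * s, (j + 0.5) * s, (k + 0.5) * s)
            for i in range(n1)
            for j in range(n2)
            for k in range(n3)
        ]
    )
    n_sub = max(2, math.ceil(s / spec.target_h))
    axis_points = [np.linspace(0.0, dims[k], (n1, n2, n3)[k] * n_sub + 1) for k in range(3)]

    def keep(cpts):
        d2 = ((cpts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        return ~np.any(d2 <= r * r, axis=1)

    nodes, conn = _structured_mesh(axis_points, keep)
    facets = _boundary_facets(conn, 3)
    centroids = nodes[facets].mean(axis=1)
    on_box = np.zeros(centroids.shape[0], dtype=bool)
    for k in range(3):
        on_box |= np.isclose(centroids[:, k], 0.0, atol=1e-9 * dims[k])
        on_box |= np.isclose(centroids[:, k], dims[k], atol=1e-9 * dims[k])
    d2 = ((centroids[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    tags = np.where(on_box, TAG_BOX, CELL_TAG_BASE + nearest)
    types = assign_cell_types(
        spec.n_cells, spec.fraction_secreting, spec.fraction_regulatory, spec.rng_seed
    )
    mesh = Mesh(nodes, conn, facets, tags.astype(int), dim=3)
    mesh.metadata["cells"] = {
        "centers": centers.tolist(),
        "radius": r,
        "spacing": s,
        "grid": [n1, n2, n3],
        "types": types,
        "tags": [int(CELL_TAG_BASE + k) for k in range(spec.n_cells)],
        "rng_seed": int(spec.rng_seed),
    }
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# Graph distances (geometry effect on signaling distance)
# ---------------------------------------------------------------------------


def max_graph_distance_from(mesh: Mesh, tag: int) -> float:
    """Longest shortest-path distance (over mesh edges) from the tagged surface.

    A proxy for the geodesic distance a molecule must travel from the
    nuclear interface; cytoplasmic extensions strictly increase it.
    """
    e = mesh.edges()
    w = np.linalg.norm(mesh.nodes[e[:, 0]] - mesh.nodes[e[:, 1]], axis=1)
    n = mesh.n_nodes
    g = coo_matrix((np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])), shape=(n, n))
    sources = mesh.boundary_nodes(tag)
    dist = dijkstra(g.tocsr(), directed=False, indices=sources, min_only=True)
    return float(dist.max())
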